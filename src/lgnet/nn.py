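"""Neural-network layers, parameter management and SGD on top of `lgnet.tensor`.

Layers follow the familiar Module convention: parameters are discovered by
attribute traversal, `state_dict` / `load_state_dict` move weights in and out
as plain numpy arrays, and `train()` / `eval()` switch batch-normalisation
between batch and running statistics.  Initialisation is always driven by an
explicit `numpy.random.Generator` so every model build is reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _unbroadcast

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "ReLU",
    "conv2d",
    "global_avg_pool",
    "SGD",
]


class Parameter(Tensor):
    """A tensor registered as learnable by Module traversal."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -------------------------------------------------------- mode switches
    def train(self, mode: bool = True):
        self.training = mode
        for m in self._submodules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # ---------------------------------------------------------- collections
    def _submodules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            path = f"{prefix}{k}" if prefix else k
            if isinstance(v, Parameter):
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_parameters(path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # --------------------------------------------------------- serialisation
    def _named_buffers(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            path = f"{prefix}{k}" if prefix else k
            if isinstance(v, np.ndarray):
                yield path, v
            elif isinstance(v, Module):
                yield from v._named_buffers(path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{path}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        for k, buf in self._named_buffers():
            state[k] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(p.data.dtype, copy=True)
        for k, buf in buffers.items():
            buf[...] = state[k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m):
        self.items.append(m)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = ModuleList(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


# --------------------------------------------------------------------------
# functional 2-D convolution (im2col forward, col2im backward)
# --------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of an NCHW batch with an OIkk kernel."""
    N, C, H, W = x.shape
    O, Ci, kh, kw = weight.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input has {C}, kernel expects {Ci}")
    sh = sw = stride
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::sh, ::sw]                       # N,C,Ho,Wo,kh,kw
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
    wmat = weight.data.reshape(O, -1)
    out_mat = cols @ wmat.T
    if bias is not None:
        out_mat = out_mat + bias.data
    out_data = out_mat.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)

    prev = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, _prev=prev)

    def _bw(g):
        g_mat = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, O)
        if bias is not None and bias.requires_grad:
            bias._accumulate(_unbroadcast(g_mat.sum(axis=0), bias.shape))
        if weight.requires_grad:
            weight._accumulate((g_mat.T @ cols).reshape(weight.shape))
        if x.requires_grad:
            dcols = (g_mat @ wmat).reshape(N, Ho, Wo, C, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:Hp - padding, padding:Wp - padding]
            x._accumulate(dxp)

    out._backward = _bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC mean over the spatial axes."""
    return x.mean(axis=(2, 3))


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels, k, k), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        shape = (1, c, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean[...] = ((1 - self.momentum) * self.running_mean
                                      + self.momentum * mu.data.reshape(-1))
            self.running_var[...] = ((1 - self.momentum) * self.running_var
                                     + self.momentum * var.data.reshape(-1))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = Tensor(self.running_mean.reshape(shape).astype(x.dtype))
            var = Tensor(self.running_var.reshape(shape).astype(x.dtype))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


# --------------------------------------------------------------------------
# optimiser
# --------------------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with momentum and decoupled L2 weight decay.

    `param_groups` is a list of dicts with keys ``params`` (list of
    (name, Parameter) pairs or Parameters) and ``lr``; momentum and weight
    decay are shared across groups.
    """

    def __init__(self, param_groups, momentum: float = 0.9, weight_decay: float = 0.0):
        self.groups = []
        for g in param_groups:
            params = [(p if isinstance(p, tuple) else (None, p)) for p in g["params"]]
            self.groups.append({
                "params": params,
                "lr": float(g["lr"]),
                "buffers": [np.zeros_like(p.data) for _, p in params],
            })
        self.momentum = momentum
        self.weight_decay = weight_decay

    def zero_grad(self):
        for g in self.groups:
            for _, p in g["params"]:
                p.zero_grad()

    def step(self):
        for g in self.groups:
            lr = g["lr"]
            for (_, p), buf in zip(g["params"], g["buffers"]):
                if p.grad is None:
                    continue
                grad = p.grad.astype(p.data.dtype)
                if self.weight_decay:
                    grad = grad + self.weight_decay * p.data
                buf *= self.momentum
                buf += grad
                p.data = p.data - lr * buf
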