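"""Network building blocks: conv layers, batch norm, residual blocks, Adam.

Initialisation follows He fan-in scaling and is driven by an explicit
``numpy.random.Generator`` so that model construction is reproducible from a
single integer seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module container: parameter discovery + train/eval mode flags."""

    def __init__(self):
        self.training = True

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Parameter]:
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, (list, tuple)):
                params.extend(v for v in value if isinstance(v, Parameter))
        for child in self._children():
            params.extend(child.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        named = []
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                named.append((path, value))
            elif isinstance(value, Module):
                named.extend(value.named_parameters(path + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        named.append((f"{path}.{i}", item))
                    elif isinstance(item, Module):
                        named.extend(item.named_parameters(f"{path}.{i}."))
        return named

    def train(self):
        self.training = True
        for child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for child in self._children():
            child.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- flat state dict (parameters + buffers) for checkpointing ------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for key, (holder, attr) in self._buffer_refs().items():
            state[key] = getattr(holder, attr).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        buffers = self._buffer_refs()
        for key, value in state.items():
            if key in own:
                own[key].data = np.asarray(value, dtype=np.float32).copy()
            elif key in buffers:
                holder, attr = buffers[key]
                setattr(holder, attr, np.asarray(value,
                                                 dtype=np.float32).copy())
            else:
                raise KeyError(f"unknown state entry {key!r}")

    def _buffer_refs(self, prefix: str = "") -> dict:
        refs = {}
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(value, Module):
                refs.update(value._buffer_refs(path + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        refs.update(item._buffer_refs(f"{path}.{i}."))
        if isinstance(self, BatchNorm2d):
            refs[prefix + "running_mean"] = (self, "running_mean")
            refs[prefix + "running_var"] = (self, "running_var")
        return refs


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    sd = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, sd, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(
            he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias \
            else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics for eval."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(c))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(c))
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, c, 1, 1)
        b = self.beta.reshape(1, c, 1, 1)
        return xhat * g + b


class ResBlock(Module):
    """conv-BN-ReLU-conv-BN residual unit with a strided projection skip."""

    def __init__(self, in_ch: int, out_ch: int, rng, stride: int = 1):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=1,
                            bias=False)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, padding=1, bias=False)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.skip = Conv2d(in_ch, out_ch, 1, rng, stride=stride,
                               bias=False)
            self.skip_bn = BatchNorm2d(out_ch)
        else:
            self.skip = None
            self.skip_bn = None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        s = self.skip_bn(self.skip(x)) if self.skip is not None else x
        return (h + s).relu()


class Adam:
    """Adam optimizer (bias-corrected first/second moments)."""

    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
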