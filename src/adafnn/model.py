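"""The multi-adaptive functional neural network (Multi-AdaFNN).

Each of the F input channels carries a curve :math:`X_f(t)` on [0, 1].  A
dedicated *basis layer* per channel holds K *micro-networks* — scalar-in /
scalar-out two-hidden-layer perceptrons — each defining one learnable basis
function :math:`\\beta_{f,k}(t)`.  A trial is summarized by the K·F
trapezoid inner products :math:`c_{f,k} = \\langle \\beta_{f,k}, X_f\\rangle`,
concatenated channel-major into a coefficient vector that a residual MLP
head maps to softmax probabilities over the three classes.  Bases and head
are trained jointly, so the basis functions adapt to the classification
task instead of being fixed splines or Fourier modes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, layer_norm
from .containers import FunctionalTrialSet
from .grid import TimeGrid

__all__ = [
    "MicroNetworkSpec",
    "BasisLayerSpec",
    "ClassifierHeadSpec",
    "ModelSpec",
    "MultiAdaFNN",
]

_ACTIVATIONS = {
    "tanh": Tensor.tanh,
    "relu": Tensor.relu,
    "selu": Tensor.selu,
}


@dataclass(frozen=True)
class MicroNetworkSpec:
    """One scalar-in/scalar-out basis micro-network: two hidden layers
    followed by a linear output so basis values can take either sign.

    ``time_scale`` sets the initialization range of the first-layer weights
    and biases: it is a temporal-resolution prior, bounding the sharpest
    transition a freshly initialized basis can express to about
    1/time_scale of the [0, 1] interval.  With the fan-in rule (bound 1 for
    a scalar input) the initial bases are nearly linear in t and localized
    features emerge impractically slowly at the configured learning rate.
    """

    hidden_widths: tuple[int, int] = (16, 8)
    activation: str = "tanh"
    time_scale: float = 30.0

    def __post_init__(self):
        if len(self.hidden_widths) != 2 or min(self.hidden_widths) < 1:
            raise ValueError("micro-networks have exactly two positive hidden widths")
        if self.activation not in ("tanh", "relu", "selu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.time_scale <= 0:
            raise ValueError("time_scale must be positive")


@dataclass(frozen=True)
class BasisLayerSpec:
    """F channels x K micro-networks; the same K for every channel keeps the
    representation balanced across channels.

    ``layer_norm`` applies the basis-layer normalization: each basis
    function is divided by its root-mean-square over the grid before the
    inner products, giving every basis a uniform scale.  Classification is
    then insensitive to overall basis amplitude, so the L1 sparsity penalty
    acts purely on basis *shape* — concentrating mass — rather than being
    satisfiable by global shrinkage.
    """

    K: int
    F: int
    micro: MicroNetworkSpec = MicroNetworkSpec()
    layer_norm: bool = True

    def __post_init__(self):
        if self.K < 1 or self.F < 1:
            raise ValueError("K and F must be positive")


@dataclass(frozen=True)
class ClassifierHeadSpec:
    """Residual MLP on the fused coefficient vector.

    ``coeff_layer_norm`` normalizes the coefficient vector before the MLP
    (coefficient scales differ across modalities); ``use_layer_norm`` adds
    layer normalization after each hidden activation.  Residual skips use a
    linear projection when consecutive widths differ.
    """

    hidden_widths: tuple[int, int] = (32, 16)
    activation: str = "relu"
    dropout_rate: float = 0.20
    use_layer_norm: bool = True
    use_residual: bool = True
    coeff_layer_norm: bool = True
    n_classes: int = 3

    def __post_init__(self):
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.activation not in ("relu", "selu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class ModelSpec:
    basis: BasisLayerSpec
    head: ClassifierHeadSpec = ClassifierHeadSpec()


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class MultiAdaFNN:
    """Parameter container + forward pass.

    Parameters are float64 numpy arrays wrapped in autodiff tensors;
    initialization is fan-in-scaled uniform from a seeded generator, so a
    given (spec, seed) pair always yields the same model.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        F, K = spec.basis.F, spec.basis.K
        h1, h2 = spec.basis.micro.hidden_widths
        p: dict[str, Tensor] = {}
        # basis micro-networks, stacked over (F, K); first layer initialized
        # at the temporal-resolution scale so kinks spread over [0, 1]
        ts = spec.basis.micro.time_scale
        p["bW1"] = _uniform(rng, (F, K, 1, h1), 1.0 / ts**2)
        p["bb1"] = _uniform(rng, (F, K, 1, h1), 1.0 / ts**2)
        p["bW2"] = _uniform(rng, (F, K, h1, h2), h1)
        p["bb2"] = _uniform(rng, (F, K, 1, h2), h1)
        p["bW3"] = _uniform(rng, (F, K, h2, 1), h2)
        p["bb3"] = _uniform(rng, (F, K, 1, 1), h2)
        # MLP head
        D = F * K
        head = spec.head
        if head.coeff_layer_norm:
            p["lnc_g"] = Tensor(np.ones(D), requires_grad=True)
            p["lnc_b"] = Tensor(np.zeros(D), requires_grad=True)
        d_in = D
        for i, w in enumerate(head.hidden_widths):
            p[f"W{i}"] = _uniform(rng, (d_in, w), d_in)
            p[f"b{i}"] = _uniform(rng, (w,), d_in)
            if head.use_layer_norm:
                p[f"ln{i}_g"] = Tensor(np.ones(w), requires_grad=True)
                p[f"ln{i}_b"] = Tensor(np.zeros(w), requires_grad=True)
            if head.use_residual and d_in != w:
                p[f"P{i}"] = _uniform(rng, (d_in, w), d_in)
            d_in = w
        p["W_out"] = _uniform(rng, (d_in, head.n_classes), d_in)
        p["b_out"] = _uniform(rng, (head.n_classes,), d_in)
        self.params = p

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=np.float64).copy()

    # -- forward components --------------------------------------------------

    def basis_tensor(self, grid: TimeGrid) -> Tensor:
        """Evaluate every micro-network on the grid: an (F, K, J) tensor in
        the autodiff graph so penalties and the loss backpropagate into it."""
        for name, t in self.params.items():
            if not np.isfinite(t.data).all():
                raise FloatingPointError(f"non-finite parameter in {name}")
        act = _ACTIVATIONS[self.spec.basis.micro.activation]
        p = self.params
        t_in = Tensor(grid.points.reshape(1, 1, grid.J, 1))
        h = act(t_in @ p["bW1"] + p["bb1"])
        h = act(h @ p["bW2"] + p["bb2"])
        out = h @ p["bW3"] + p["bb3"]  # (F, K, J, 1)
        F, K = self.spec.basis.F, self.spec.basis.K
        out = out.reshape(F, K, grid.J)
        if self.spec.basis.layer_norm:
            # basis-layer normalization: unit RMS over the grid per basis
            rms = ((out**2).mean(axis=-1, keepdims=True) + 1e-12).sqrt()
            out = out / rms
        return out

    def evaluate_bases(self, grid: TimeGrid) -> np.ndarray:
        """Basis functions evaluated on the grid, as a plain (F, K, J) array."""
        return self.basis_tensor(grid).data.copy()

    def coefficient_tensor(self, values: np.ndarray, grid: TimeGrid,
                           bases: Tensor | None = None) -> Tensor:
        """Trapezoid inner products of every basis with every trial curve.

        ``values`` is (n, J, F); the result is (n, F·K), channel-major
        (entry f·K + k is the k-th basis coefficient of channel f).
        """
        values = np.asarray(values, dtype=np.float64)
        if values.ndim == 2:
            values = values[None]
        F, K = self.spec.basis.F, self.spec.basis.K
        n, J, Fv = values.shape
        if Fv != F or J != grid.J:
            raise ValueError(
                f"trials have shape (J={J}, F={Fv}) but model expects "
                f"(J={grid.J}, F={F})"
            )
        if bases is None:
            bases = self.basis_tensor(grid)
        # (F,K,J) @ (F,J,n) -> (F,K,n); quadrature weights folded into data
        Xw = np.einsum("njf,j->fjn", values, grid.weights)
        c = bases @ Tensor(Xw)
        return c.transpose((2, 0, 1)).reshape(n, F * K)

    def compute_coefficients(self, trial: np.ndarray, grid: TimeGrid) -> np.ndarray:
        """Coefficient vector (length K·F) for a single J x F trial."""
        return self.coefficient_tensor(trial, grid).data.reshape(-1).copy()

    def logits(self, values: np.ndarray, grid: TimeGrid, train_mode: bool = False,
               dropout_rng: np.random.Generator | None = None,
               bases: Tensor | None = None) -> Tensor:
        """Forward pass to pre-softmax logits, shape (n, n_classes)."""
        head = self.spec.head
        act = _ACTIVATIONS[head.activation]
        p = self.params
        x = self.coefficient_tensor(values, grid, bases=bases)
        if head.coeff_layer_norm:
            x = layer_norm(x, p["lnc_g"], p["lnc_b"])
        for i in range(len(head.hidden_widths)):
            h = act(x @ p[f"W{i}"] + p[f"b{i}"])
            if head.use_layer_norm:
                h = layer_norm(h, p[f"ln{i}_g"], p[f"ln{i}_b"])
            if train_mode and head.dropout_rate > 0.0:
                if dropout_rng is None:
                    raise ValueError("train_mode dropout needs a dropout_rng")
                keep = 1.0 - head.dropout_rate
                mask = dropout_rng.random(h.shape) < keep
                h = h * Tensor(mask / keep)
            if head.use_residual:
                skip = x @ p[f"P{i}"] if f"P{i}" in p else x
                h = h + skip
            if not np.isfinite(h.data).all():
                raise FloatingPointError(f"non-finite activation in MLP layer {i}")
            x = h
        z = x @ p["W_out"] + p["b_out"]
        if not np.isfinite(z.data).all():
            raise FloatingPointError("non-finite logits at output layer")
        return z

    def forward(self, trial: np.ndarray, grid: TimeGrid, train_mode: bool = False,
                dropout_rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities for a single J x F trial (3-vector)."""
        z = self.logits(trial, grid, train_mode=train_mode,
                        dropout_rng=dropout_rng).data[0]
        e = np.exp(z - z.max())
        return e / e.sum()

    def predict_proba(self, values: np.ndarray, grid: TimeGrid) -> np.ndarray:
        z = self.logits(values, grid).data
        e = np.exp(z - z.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, trials: FunctionalTrialSet) -> tuple[np.ndarray, np.ndarray]:
        """Argmax labels (ties broken toward the lowest class index) and the
        probability matrix for every trial in the set."""
        if trials.n == 0:
            raise ValueError("empty trial set")
        probs = self.predict_proba(trials.values, trials.grid)
        return probs.argmax(axis=1), probs

    # -- checkpointing -----------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        np.savez_compressed(path, **self.state_dict())
        sidecar = {
            "basis": asdict(self.spec.basis),
            "head": asdict(self.spec.head),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "MultiAdaFNN":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        basis = sidecar["basis"]
        micro = MicroNetworkSpec(
            tuple(basis["micro"]["hidden_widths"]),
            basis["micro"]["activation"],
            basis["micro"].get("time_scale", 30.0),
        )
        spec = ModelSpec(
            basis=BasisLayerSpec(basis["K"], basis["F"], micro,
                                 basis.get("layer_norm", True)),
            head=ClassifierHeadSpec(**{
                **sidecar["head"],
                "hidden_widths": tuple(sidecar["head"]["hidden_widths"]),
            }),
        )
        model = cls(spec)
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            model.load_state_dict({k: z[k] for k in z.files})
        return model
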