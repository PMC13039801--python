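"""Per-atom Gaussian-process regression of partitioned atomic energies.

The model follows the Model/Results convention: :class:`MolecularGPR`
holds the data and model specification, ``fit()`` returns a
:class:`MolecularGPRResults` carrying per-atom weights, hyperparameters
and diagnostics.

Science summary
---------------
Each atom A has its own GP over ALF features R with posterior mean

    Ê_A(R) = m_A + Σ_i ω_i k(R^i, R),

where the composite kernel

    k(R^i, R^j) = σ_f · exp(−Σ_d θ_d Φ_d),
    Φ_d = sin²(0.5 (R_d^i − R_d^j))   for azimuthal (periodic) features,
        = (R_d^i − R_d^j)²            otherwise,

and the prior mean m_A is one of six statistics of the atom's training
energies (MF1…MF5, MIN).  Far from the training data the kernel terms
vanish and the prediction reverts to m_A — the prior mean is therefore
the model's extrapolation behaviour, and shifting it above the training
energies (MF4/MF5) builds a restoring wall around the trained region.
The molecular energy is the sum of atomic predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from . import io as aio
from .alf import ALFDefinition, build_alf, featurize_all, n_features, periodic_mask
from .io import Geometry, LabeledConfiguration
from .labels import correct_energies

MEAN_KINDS = ("MF1", "MF2", "MF3", "MF4", "MF5", "MIN")

SIGMA_N2_BOUNDS = (1e-10, 1e-4)
JITTER_CAP = 1e-6


# ---------------------------------------------------------------------------
# Mean functions


@dataclass(frozen=True)
class MeanFunctionSpec:
    kind: str
    value: float  # Ha


def compute_mean(kind: str, training_energies) -> MeanFunctionSpec:
    """Prior mean statistic of an atom's training energies.

    MF1 = μ; MF2 = μ + σ (population); MF3 = max; MF4 = max + H;
    MF5 = max + 5H; MIN = min — with H the range max − min.
    """
    e = np.asarray(training_energies, float)
    if e.size == 0:
        raise ValueError("empty training-energy set")
    if kind not in MEAN_KINDS:
        raise ValueError(f"unknown mean-function kind {kind!r}; use one of {MEAN_KINDS}")
    mu, mx, mn = e.mean(), e.max(), e.min()
    if kind == "MF1":
        v = mu
    elif kind == "MF2":
        v = mu + e.std()  # population σ (divisor N)
    elif kind == "MF3":
        v = mx
    elif kind == "MF4":
        v = mx + (mx - mn)
    elif kind == "MF5":
        v = mx + 5.0 * (mx - mn)
    else:  # MIN
        v = mn
    return MeanFunctionSpec(kind, float(v))


# ---------------------------------------------------------------------------
# Kernel


@dataclass
class KernelParams:
    theta: np.ndarray  # (F,), each in [0, 1]
    sigma_f: float
    sigma_n2: float

    def __post_init__(self):
        self.theta = np.asarray(self.theta, float)


def default_sigma_f(n_train: int, n_feats: int) -> float:
    """Fixed kernel pre-factor σ_f = (N_train · N_feats)^0.5."""
    return float(np.sqrt(n_train * n_feats))


def _phi_tensor(X1, X2, mask):
    """Per-feature squared/periodic differences, shape (n1, n2, F)."""
    D = X1[:, None, :] - X2[None, :, :]
    out = D * D
    if mask.any():
        out[..., mask] = np.sin(0.5 * D[..., mask]) ** 2
    return out


def kernel(r_i, r_j, params: KernelParams, mask=None) -> float:
    """Composite kernel between two feature vectors."""
    xi = np.atleast_1d(np.asarray(getattr(r_i, "values", r_i), float))
    xj = np.atleast_1d(np.asarray(getattr(r_j, "values", r_j), float))
    if xi.shape != xj.shape:
        raise ValueError("feature length mismatch")
    if mask is None:
        mask = getattr(r_i, "periodic_mask", None)
        if mask is None:
            mask = periodic_mask(xi.size)
    phi = _phi_tensor(xi[None], xj[None], np.asarray(mask, bool))[0, 0]
    return float(params.sigma_f * np.exp(-(phi @ params.theta)))


def kernel_matrix(X1, X2, theta, sigma_f, mask):
    phi = _phi_tensor(np.asarray(X1, float), np.asarray(X2, float), mask)
    return sigma_f * np.exp(-(phi @ np.asarray(theta, float)))


def fit_weights(K, y, mean_value, sigma_n2):
    """Solve (K + σ_n² I) ω = y − m with jitter escalation on failure."""
    n = K.shape[0]
    rhs = np.asarray(y, float) - mean_value
    jitter = sigma_n2
    while True:
        try:
            c, low = cho_factor(K + jitter * np.eye(n), lower=True)
            return cho_solve((c, low), rhs)
        except LinAlgError:
            if jitter >= JITTER_CAP:
                cond = np.linalg.cond(K + jitter * np.eye(n))

                raise LinAlgError(
                    f"kernel matrix not positive definite even at jitter "
                    f"{jitter:g} (condition estimate {cond:.3g})"
                )
            jitter = max(jitter * 10.0, 1e-12)


# ---------------------------------------------------------------------------
# Per-atom model container


@dataclass
class AtomicGPRModel:
    atom: int
    element: str
    params: KernelParams
    mean: MeanFunctionSpec
    X_train: np.ndarray  # (Ntr, F)
    weights: np.ndarray  # (Ntr,)

    def predict(self, features) -> float:
        """Posterior-mean atomic energy at one feature vector (Ha)."""
        x = np.atleast_1d(np.asarray(getattr(features, "values", features), float))
        if x.size != self.X_train.shape[1]:
            raise ValueError(
                f"feature length {x.size} does not match training "
                f"dimension {self.X_train.shape[1]}"
            )
        mask = periodic_mask(x.size)
        k = kernel_matrix(self.X_train, x[None], self.params.theta,
                          self.params.sigma_f, mask)[:, 0]
        return float(self.mean.value + self.weights @ k)


# ---------------------------------------------------------------------------
# Model


class MolecularGPR:
    """GP atomic-energy model specification bound to a labeled dataset.

    Parameters
    ----------
    configs : list of LabeledConfiguration
        Training data; per-atom raw energies are recovery-corrected
        before fitting.
    mean_function : str
        One of MF1…MF5, MIN.
    sigma_f : float, optional
        Kernel pre-factor; defaults to (N_train·N_feats)^0.5.
    alf : ALFDefinition, optional
        Frame definition; inferred from the first configuration's
        connectivity when omitted.  A 2-atom system engages the
        distance-only degenerate mode.
    """

    def __init__(self, configs, mean_function="MF5", sigma_f=None, alf=None):
        if not configs:
            raise ValueError("need at least one labeled configuration")
        if mean_function not in MEAN_KINDS:
            raise ValueError(
                f"unknown mean-function kind {mean_function!r}; "
                f"use one of {MEAN_KINDS}"
            )
        self.configs = list(configs)
        g0 = self.configs[0].geometry
        for c in self.configs[1:]:
            if c.geometry.elements != g0.elements:
                raise ValueError("all configurations must share the element list")
        self.mean_function = mean_function
        self.alf = alf if alf is not None else build_alf(g0)
        self.n_atoms = g0.n_atoms
        self.elements = list(g0.elements)
        self.n_feats = n_features(self.n_atoms, self.alf.diatomic)
        self._sigma_f_user = sigma_f

        # corrected per-atom targets and features
        self.Y = np.stack(
            [correct_energies(c).corrected_atomic_energies for c in self.configs]
        )  # (Ncfg, Natoms)
        self.X = np.stack(
            [featurize_all(c.geometry, self.alf) for c in self.configs]
        )  # (Ncfg, Natoms, F)
        self.mask = periodic_mask(self.n_feats)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        theta=None,
        sigma_n2=1e-8,
        optimize=False,
        n_validation=None,
        iterations=200,
        agents=50,
        lucky_period=5,
        lucky_count=5,
        seed=0,
    ) -> "MolecularGPRResults":
        """Fit per-atom weights; optionally grey-wolf-optimize θ and σ_n².

        Without ``optimize`` the supplied (or default, all-ones) θ and
        σ_n² are used directly.  With ``optimize`` the configurations are
        split into a training block and ``n_validation`` validation
        configurations (default: 25%, shared across atoms), and each
        atom's (θ, σ_n²) minimizes the validation mean-squared error via
        the grey-wolf search.
        """
        ncfg = len(self.configs)
        if ncfg < 2:
            raise ValueError("need at least 2 configurations to fit")
        if optimize:
            from .gwo import optimize_atomic_hyperparameters

            if n_validation is None:
                n_validation = max(1, ncfg // 4)
            rng = np.random.default_rng(seed)
            perm = rng.permutation(ncfg)
            val_idx = np.sort(perm[:n_validation])
            tr_idx = np.sort(perm[n_validation:])
        else:
            tr_idx = np.arange(ncfg)
            val_idx = np.array([], int)

        Xtr, Ytr = self.X[tr_idx], self.Y[tr_idx]
        ntr = len(tr_idx)
        sigf = (
            self._sigma_f_user
            if self._sigma_f_user is not None
            else default_sigma_f(ntr, self.n_feats)
        )
        if theta is None:
            theta0 = np.ones(self.n_feats)
        else:
            theta0 = np.broadcast_to(np.asarray(theta, float), (self.n_feats,)).copy()

        atomic_models = []
        loss_traces = []
        for a in range(self.n_atoms):
            mean = compute_mean(self.mean_function, Ytr[:, a])
            th, s_n2, trace = theta0, sigma_n2, None
            if optimize:
                ctx = AtomicLossContext(
                    Xtr[:, a, :], Ytr[:, a],
                    self.X[val_idx][:, a, :], self.Y[val_idx][:, a],
                    mean.value, sigf, self.mask,
                )
                th, s_n2, trace = optimize_atomic_hyperparameters(
                    ctx, iterations=iterations, agents=agents,
                    lucky_period=lucky_period, lucky_count=lucky_count,
                    seed=seed + a,
                )
            K = kernel_matrix(Xtr[:, a, :], Xtr[:, a, :], th, sigf, self.mask)
            w = fit_weights(K, Ytr[:, a], mean.value, s_n2)
            atomic_models.append(
                AtomicGPRModel(
                    a, self.elements[a], KernelParams(th, sigf, s_n2), mean,
                    Xtr[:, a, :].copy(), w,
                )
            )
            loss_traces.append(trace)
        return MolecularGPRResults(
            elements=self.elements,
            alf=self.alf,
            atomic_models=atomic_models,
            mean_function=self.mean_function,
            loss_traces=loss_traces,
        )


class AtomicLossContext:
    """Validation-MSE loss for one atom's hyperparameter search.

    Refits the regression weights on the training block for every
    candidate (θ, σ_n²) and scores the mean squared error on the held
    out validation block (Ha²).  Feature-difference tensors are
    precomputed once.
    """

    def __init__(self, Xtr, ytr, Xval, yval, mean_value, sigma_f, mask):
        self.phi_tr = _phi_tensor(Xtr, Xtr, mask)
        self.phi_val = _phi_tensor(Xval, Xtr, mask)
        self.ytr = np.asarray(ytr, float)
        self.yval = np.asarray(yval, float)
        self.mean_value = mean_value
        self.sigma_f = sigma_f
        self.n_feats = Xtr.shape[1]

    def loss(self, theta, sigma_n2) -> float:
        try:
            K = self.sigma_f * np.exp(-(self.phi_tr @ theta))
            w = fit_weights(K, self.ytr, self.mean_value, sigma_n2)
            kv = self.sigma_f * np.exp(-(self.phi_val @ theta))
            pred = self.mean_value + kv @ w
            val = float(np.mean((self.yval - pred) ** 2))
        except (LinAlgError, FloatingPointError):
            return np.inf
        return val if np.isfinite(val) else np.inf


# ---------------------------------------------------------------------------
# Results


@dataclass
class MolecularGPRResults:
    """Fitted per-atom GP models plus prediction/force/simulation surface."""

    elements: list[str]
    alf: ALFDefinition
    atomic_models: list[AtomicGPRModel]
    mean_function: str
    loss_traces: list = field(default_factory=list)

    def __post_init__(self):
        self._packed_cache = None

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def aggregate_mean(self) -> float:
        """M = Σ_A m_A (Ha): the far-field molecular energy."""
        return float(sum(m.mean.value for m in self.atomic_models))

    # -- prediction --------------------------------------------------------

    def _check_geometry(self, geometry: Geometry):
        if geometry.elements != self.elements:
            raise ValueError(
                f"geometry elements {geometry.elements} do not match the "
                f"model's {self.elements}"
            )

    def predict_atomic(self, geometry: Geometry) -> np.ndarray:
        """Per-atom posterior-mean energies (Ha)."""
        self._check_geometry(geometry)
        feats = featurize_all(geometry, self.alf)
        mask = periodic_mask(feats.shape[1])
        out = np.empty(self.n_atoms)
        for a, m in enumerate(self.atomic_models):
            k = kernel_matrix(m.X_train, feats[a][None], m.params.theta,
                              m.params.sigma_f, mask)[:, 0]
            out[a] = m.mean.value + m.weights @ k
        return out

    def predict(self, geometries) -> np.ndarray:
        """Molecular energies (Ha) for one Geometry or a list of them."""
        single = isinstance(geometries, Geometry)
        geoms = [geometries] if single else list(geometries)
        out = np.array([self.predict_atomic(g).sum() for g in geoms])
        return out[0] if single else out

    # -- packed arrays for the jit core ------------------------------------

    def packed(self):
        if self._packed_cache is None:
            alf_x, alf_p, others = self.alf.packed()
            Xtr = np.stack([m.X_train for m in self.atomic_models])
            W = np.stack([m.weights for m in self.atomic_models])
            theta = np.stack([m.params.theta for m in self.atomic_models])
            sigf = np.array([m.params.sigma_f for m in self.atomic_models])
            self._packed_cache = (
                alf_x, alf_p, others, Xtr, W, theta, sigf,
                self.aggregate_mean, self.alf.diatomic,
            )
        return self._packed_cache

    def energy_gradient(self, coords: np.ndarray, include_mean: bool = True):
        """(E [Ha], dE/dx [Ha/Å]) at Cartesian coordinates (N, 3) in Å.

        ``include_mean=False`` returns the energy relative to the
        aggregate prior mean M (the gradient is unaffected); useful when
        differencing energies numerically, where the constant M would
        otherwise dominate the floating-point budget.
        """
        from ._core import gp_energy_gradient
        from .units import BOHR_PER_ANGSTROM

        packed = self.packed()
        if not include_mean:
            packed = packed[:7] + (0.0,) + packed[8:]
        coords_b = np.ascontiguousarray(coords, float) * BOHR_PER_ANGSTROM
        e, grad_b = gp_energy_gradient(coords_b, *packed)
        return e, grad_b * BOHR_PER_ANGSTROM

    def forces(self, geometry: Geometry):
        from .forces import forces as _forces

        return _forces(self, geometry)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Molecular GP atomic-energy model",
            f"  atoms: {self.n_atoms} ({' '.join(self.elements)})",
            f"  mean function: {self.mean_function}   "
            f"aggregate mean M = {self.aggregate_mean:.8f} Ha",
            f"  training configurations: {self.atomic_models[0].X_train.shape[0]}"
            f"   features/atom: {self.atomic_models[0].X_train.shape[1]}",
            "",
            f"{'atom':>4} {'el':>3} {'m_A (Ha)':>14} {'sigma_f':>9} "
            f"{'sigma_n2':>10} {'theta_min':>10} {'theta_max':>10} {'|w|':>10}",
        ]
        for m in self.atomic_models:
            lines.append(
                f"{m.atom:>4} {m.element:>3} {m.mean.value:>14.8f} "
                f"{m.params.sigma_f:>9.3f} {m.params.sigma_n2:>10.2e} "
                f"{m.params.theta.min():>10.4f} {m.params.theta.max():>10.4f} "
                f"{np.linalg.norm(m.weights):>10.3e}"
            )
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "elements": self.elements,
            "mean_function": self.mean_function,
            "alf": {
                "x_axis": list(self.alf.x_axis),
                "xy_plane": list(self.alf.xy_plane),
                "diatomic": self.alf.diatomic,
            },
            "atomic_models": [
                {
                    "atom": m.atom,
                    "element": m.element,
                    "mean_kind": m.mean.kind,
                    "mean_value": m.mean.value,
                    "theta": m.params.theta.tolist(),
                    "sigma_f": m.params.sigma_f,
                    "sigma_n2": m.params.sigma_n2,
                    "X_train": m.X_train.tolist(),
                    "weights": m.weights.tolist(),
                }
                for m in self.atomic_models
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MolecularGPRResults":
        alf = ALFDefinition(
            tuple(d["alf"]["x_axis"]), tuple(d["alf"]["xy_plane"]),
            d["alf"]["diatomic"],
        )
        models = [
            AtomicGPRModel(
                am["atom"], am["element"],
                KernelParams(np.array(am["theta"]), am["sigma_f"], am["sigma_n2"]),
                MeanFunctionSpec(am["mean_kind"], am["mean_value"]),
                np.array(am["X_train"]), np.array(am["weights"]),
            )
            for am in d["atomic_models"]
        ]
        return cls(d["elements"], alf, models, d["mean_function"])

    def save(self, path) -> None:
        aio.save_model(self, path)

    @classmethod
    def load(cls, path) -> "MolecularGPRResults":
        return aio.load_model(path)
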