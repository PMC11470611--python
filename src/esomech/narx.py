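"""NARX surrogate network with Bayesian-regularized Levenberg-Marquardt training.

The network is a single-input single-output nonlinear autoregression with
exogenous input: at each step it sees tapped-delay samples of the strain
input u and of the stress output y, passes them through one hidden layer of
``tansig`` (hyperbolic-tangent sigmoid) neurons and a linear output neuron::

    y_hat(t) = LW_out . tansig(IW . u_lags(t) + LW_fb . y_lags(t) + b1) + b2

The default architecture is 1-5-1 with delay lines {1, 2} on both the input
and the feedback, giving 5*(2+2) + 5 + 5 + 1 = 31 adjustable parameters.

Training runs *open loop* (series-parallel): the delayed feedback is taken
from the measured targets, which makes the residual a deterministic,
differentiable function of the weights and permits exact Jacobians.
Evaluation runs *closed loop*: the network feeds back its own predictions.

The trainer minimizes the regularized objective ``F(w) = beta E_D +
alpha E_w`` (E_D sum of squared errors, E_w sum of squared weights) with
Levenberg-Marquardt steps; after each accepted step the hyper-parameters are
re-estimated by the evidence (Bayes) update

    gamma = k - 2 alpha tr(H^-1),   alpha = gamma / (2 E_w),
    beta  = (N - gamma) / (2 E_D),  H = 2 beta J'J + 2 alpha I,

where ``gamma`` is the effective number of parameters out of ``k`` and
``N`` the number of training residuals.  Starting values are ``alpha = 0``,
``beta = 1``, so the first epoch sees the plain least-squares objective and
``gamma`` starts exactly at ``k``.
"""

from __future__ import annotations

import io
import os
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg


# ---------------------------------------------------------------------------
# architecture and weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NarxArchitecture:
    """1-H-1 tapped-delay architecture.

    ``input_delays`` may include lag 0 (an undelayed exogenous tap);
    feedback lags must be strictly positive.
    """

    n_hidden: int = 5
    input_delays: tuple[int, ...] = (1, 2)
    feedback_delays: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("need at least one hidden neuron")
        if not self.input_delays or not self.feedback_delays:
            raise ValueError("delay sets must be non-empty")
        if any(d < 0 for d in self.input_delays):
            raise ValueError("input delays must be >= 0")
        if any(d < 1 for d in self.feedback_delays):
            raise ValueError("feedback delays must be >= 1")

    @property
    def max_delay(self) -> int:
        return max((*self.input_delays, *self.feedback_delays))


def count_parameters(arch: NarxArchitecture) -> int:
    """Total number of adjustable weights and biases."""
    h = arch.n_hidden
    return h * (len(arch.input_delays) + len(arch.feedback_delays)) + 2 * h + 1


@dataclass
class NarxWeights:
    """Weight matrices and biases; shapes are fixed by the architecture."""

    arch: NarxArchitecture
    IW: np.ndarray  # (n_hidden, n_input_delays)
    LW_fb: np.ndarray  # (n_hidden, n_feedback_delays)
    b1: np.ndarray  # (n_hidden,)
    LW_out: np.ndarray  # (n_hidden,)
    b2: float

    def __post_init__(self) -> None:
        h = self.arch.n_hidden
        self.IW = np.asarray(self.IW, dtype=float).reshape(h, len(self.arch.input_delays))
        self.LW_fb = np.asarray(self.LW_fb, dtype=float).reshape(
            h, len(self.arch.feedback_delays)
        )
        self.b1 = np.asarray(self.b1, dtype=float).reshape(h)
        self.LW_out = np.asarray(self.LW_out, dtype=float).reshape(h)
        self.b2 = float(self.b2)
        for block in (self.IW, self.LW_fb, self.b1, self.LW_out):
            if not np.all(np.isfinite(block)):
                raise ValueError("weights must be finite")

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.IW.ravel(), self.LW_fb.ravel(), self.b1, self.LW_out, [self.b2]]
        )

    @classmethod
    def from_vector(cls, arch: NarxArchitecture, vec: np.ndarray) -> "NarxWeights":
        vec = np.asarray(vec, dtype=float)
        if vec.size != count_parameters(arch):
            raise ValueError(
                f"expected {count_parameters(arch)} parameters, got {vec.size}"
            )
        h = arch.n_hidden
        ni, nf = len(arch.input_delays), len(arch.feedback_delays)
        o = 0
        IW = vec[o : o + h * ni].reshape(h, ni)
        o += h * ni
        LW_fb = vec[o : o + h * nf].reshape(h, nf)
        o += h * nf
        b1 = vec[o : o + h]
        o += h
        LW_out = vec[o : o + h]
        o += h
        return cls(arch=arch, IW=IW, LW_fb=LW_fb, b1=b1, LW_out=LW_out, b2=vec[o])


def init_weights(arch: NarxArchitecture, seed: int) -> NarxWeights:
    """Reproducible uniform draw in [-0.5, 0.5] for every weight and bias."""
    rng = np.random.default_rng(seed)
    vec = rng.uniform(-0.5, 0.5, size=count_parameters(arch))
    return NarxWeights.from_vector(arch, vec)


def tansig(x):
    """Hyperbolic-tangent sigmoid, ``2/(1+exp(-2x)) - 1``; saturates safely."""
    return np.tanh(x)


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------


def _lagged_matrices(
    arch: NarxArchitecture, u: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Delay-line design matrices for rows t = max_delay .. n-1."""
    d = arch.max_delay
    n = u.size
    t = np.arange(d, n)
    U = np.stack([u[t - k] for k in arch.input_delays], axis=1)
    Y = np.stack([y[t - k] for k in arch.feedback_delays], axis=1)
    return U, Y


def _hidden_and_output(
    w: NarxWeights, U: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    A = tansig(U @ w.IW.T + Y @ w.LW_fb.T + w.b1)
    return A, A @ w.LW_out + w.b2


def forward_open_loop(w: NarxWeights, u: np.ndarray, y_meas: np.ndarray) -> np.ndarray:
    """Series-parallel (teacher-forced) prediction over a full sequence.

    Delayed feedback is taken from the measured targets; the first
    ``max_delay`` outputs are primed with the measured values.
    """
    u = np.asarray(u, dtype=float)
    y_meas = np.asarray(y_meas, dtype=float)
    d = w.arch.max_delay
    if u.size != y_meas.size or u.size <= d:
        raise ValueError("u and y_meas must share a length exceeding the max delay")
    U, Y = _lagged_matrices(w.arch, u, y_meas)
    _, out = _hidden_and_output(w, U, Y)
    yhat = np.empty_like(y_meas)
    yhat[:d] = y_meas[:d]
    yhat[d:] = out
    return yhat


def simulate_closed_loop(
    w: NarxWeights, u: np.ndarray, y_prime: Sequence[float]
) -> np.ndarray:
    """Parallel (free-running) simulation feeding back the network's own output.

    ``y_prime`` supplies the first ``max_delay`` output values.
    """
    u = np.asarray(u, dtype=float)
    d = w.arch.max_delay
    y_prime = np.asarray(y_prime, dtype=float)
    if y_prime.size != d:
        raise ValueError(f"y_prime must provide {d} initial values")
    n = u.size
    y = np.empty(n)
    y[:d] = y_prime
    for t in range(d, n):
        u_lags = u[[t - k for k in w.arch.input_delays]]
        y_lags = y[[t - k for k in w.arch.feedback_delays]]
        a = tansig(w.IW @ u_lags + w.LW_fb @ y_lags + w.b1)
        y[t] = float(w.LW_out @ a + w.b2)
        if not np.isfinite(y[t]):
            raise FloatingPointError(f"closed-loop simulation diverged at step {t}")
    return y


def jacobian(
    w: NarxWeights, u: np.ndarray, y_meas: np.ndarray, printed_derivative: bool = False
) -> np.ndarray:
    """Exact open-loop residual Jacobian, rows t = max_delay..n-1.

    The residual is oriented ``r(t) = y_meas(t) - y_hat(t)``, so every column
    is ``-d y_hat / d w``; the column for the output bias b2 is identically
    -1.  ``printed_derivative=True`` swaps the correct tansig derivative
    ``1 - a^2`` for the logistic form ``a (1 - a)`` -- kept only to study the
    published update rule; it is not a consistent gradient and does not
    converge in general.
    """
    u = np.asarray(u, dtype=float)
    y_meas = np.asarray(y_meas, dtype=float)
    U, Y = _lagged_matrices(w.arch, u, y_meas)
    A, _ = _hidden_and_output(w, U, Y)
    dA = A * (1.0 - A) if printed_derivative else 1.0 - A**2
    back = dA * w.LW_out  # (m, h): dyhat/d(preactivation_i)
    m = U.shape[0]
    cols = [
        (back[:, :, None] * U[:, None, :]).reshape(m, -1),  # IW
        (back[:, :, None] * Y[:, None, :]).reshape(m, -1),  # LW_fb
        back,  # b1
        A,  # LW_out
        np.ones((m, 1)),  # b2
    ]
    return -np.concatenate(cols, axis=1)


# ---------------------------------------------------------------------------
# data division and noise augmentation
# ---------------------------------------------------------------------------


def divide_data(
    n: int,
    split: tuple[float, float, float] = (0.5, 0.25, 0.25),
    seed: int | np.random.SeedSequence = 0,
    max_delay: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint train/validation/test division of sequence indices.

    Divides the usable indices ``max_delay .. n-1`` (the first ``max_delay``
    samples only prime the delay lines).  Subset sizes are within one sample
    of the exact fractions.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    idx = np.arange(max_delay, n)
    m = idx.size
    if m < 8:
        raise ValueError(f"sequence too short to divide: {m} usable samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(idx)
    n_train = int(round(split[0] * m))
    n_val = int(round(split[1] * m))
    train = np.sort(perm[:n_train])
    val = np.sort(perm[n_train : n_train + n_val])
    test = np.sort(perm[n_train + n_val :])
    return train, val, test


def add_training_noise(
    y: np.ndarray, magnitude: float, seed: int | np.random.SeedSequence | np.random.Generator = 0
) -> np.ndarray:
    """Add zero-mean Gaussian noise of the given standard deviation."""
    if magnitude < 0:
        raise ValueError("noise magnitude must be non-negative")
    y = np.asarray(y, dtype=float)
    if magnitude == 0:
        return y.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return y + rng.normal(0.0, magnitude, size=y.shape)


def default_noise_magnitudes(
    cycles: int = 5, stress_scale: float | None = None, top_kpa: float = 1.0
) -> np.ndarray:
    """Log-spaced noise levels topping at ``top_kpa`` on the normalized scale.

    The noise is specified in kPa and divided by the ensemble normalisation
    constant; without a scale a typical normalized level of 0.02 is used.
    """
    top = top_kpa / stress_scale if stress_scale else 0.02
    if cycles == 1:
        return np.array([top])
    # coarse-to-fine annealing: the strongest perturbation first, the final
    # cycle on the cleanest targets
    return np.geomspace(top, top / 16.0, cycles)


# ---------------------------------------------------------------------------
# Bayesian-regularized Levenberg-Marquardt training
# ---------------------------------------------------------------------------


@dataclass
class TrainingConfig:
    """Knobs of the regularized LM trainer.

    The damping schedule (``mu``) interpolates between Gauss-Newton
    (small mu) and gradient descent (large mu); training stops when mu
    exceeds ``mu_max``, the epoch budget or error goal is reached, or the
    gradient becomes negligible.
    """

    max_epochs: int = 1000
    mse_goal: float = 0.0
    mu_init: float = 0.005
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 5e5
    min_gradient: float = 1e-10
    split: tuple[float, float, float] = (0.5, 0.25, 0.25)
    cycles: int = 5
    noise_magnitudes: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class BayesRegState:
    """Hyper-parameter state tracked across regularized training."""

    alpha: float
    beta: float
    E_D: float
    E_w: float
    gamma: float
    mu: float
    epoch: int


@dataclass
class TrainingReport:
    epochs_run: int
    final_mse: float
    final_gradient: float
    final_state: BayesRegState
    stop_reason: str
    mse_val: float | None = None
    mse_test: float | None = None
    history: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _cycle_split(
    n: int, cfg: TrainingConfig, cycle: int, max_delay: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ss = np.random.SeedSequence([int(cfg.seed), int(cycle)])
    return divide_data(n, cfg.split, seed=ss, max_delay=max_delay)


def train_bayesian_regularization(
    w0: NarxWeights,
    u: np.ndarray,
    y: np.ndarray,
    cfg: TrainingConfig,
    train_idx: np.ndarray | None = None,
    subsets: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    _cycle: int = 0,
) -> tuple[NarxWeights, TrainingReport]:
    """Open-loop LM training of ``F(w) = beta E_D + alpha E_w``.

    ``train_idx`` (sequence indices, >= max_delay) restricts the residuals
    entering E_D; when omitted, a random division per ``cfg.split`` and
    ``cfg.seed`` supplies it, and the held-out validation/test errors are
    monitored (never used for weight selection -- regularization replaces
    early stopping).
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    arch = w0.arch
    d = arch.max_delay
    n = u.size
    if y.size != n or n <= d + 8:
        raise ValueError("sequences must be aligned and longer than max delay + 8")

    if train_idx is None:
        if subsets is None:
            subsets = _cycle_split(n, cfg, _cycle, d)
        train_idx, val_idx, test_idx = subsets
    else:
        val_idx = test_idx = None
    train_rows = np.asarray(train_idx, dtype=int) - d

    k = count_parameters(arch)
    wv = w0.to_vector()
    N = train_rows.size
    alpha, beta = 0.0, 1.0
    mu = cfg.mu_init
    warnings: list[str] = []
    history: list[dict] = []

    def full_residual(vec: np.ndarray) -> np.ndarray:
        yhat = forward_open_loop(NarxWeights.from_vector(arch, vec), u, y)
        return (y - yhat)[d:]

    def objective(vec: np.ndarray, a: float, b: float) -> tuple[float, float, float]:
        r = full_residual(vec)[train_rows]
        e_d = float(r @ r)
        e_w = float(vec @ vec)
        return b * e_d + a * e_w, e_d, e_w

    F, E_D, E_w = objective(wv, alpha, beta)
    gamma = float(k)
    grad_norm = np.inf
    stop_reason = "max_epochs"
    epoch = 0
    eye = np.eye(k)

    for epoch in range(1, cfg.max_epochs + 1):
        if E_D / N <= cfg.mse_goal:
            stop_reason = "goal_met"
            epoch -= 1
            break
        J = jacobian(NarxWeights.from_vector(arch, wv), u, y)[train_rows]
        r = full_residual(wv)[train_rows]
        g = 2.0 * beta * (J.T @ r) + 2.0 * alpha * wv
        grad_norm = float(np.max(np.abs(g)))
        if grad_norm < cfg.min_gradient:
            stop_reason = "min_gradient"
            epoch -= 1
            break
        JTJ = J.T @ J
        H = 2.0 * beta * JTJ + 2.0 * alpha * eye

        accepted = False
        F_before = F
        while mu <= cfg.mu_max:
            M = H + mu * eye
            try:
                with _warnings.catch_warnings():
                    # near-singular M is routine at small mu; the step is
                    # accepted only if it actually decreases F
                    _warnings.simplefilter("ignore", linalg.LinAlgWarning)
                    step = linalg.solve(M, -g, assume_a="pos")
            except linalg.LinAlgError:
                step = -linalg.pinvh(M) @ g
                if "singular Hessian; damped pseudo-inverse used" not in warnings:
                    warnings.append("singular Hessian; damped pseudo-inverse used")
            w_try = wv + step
            F_try, E_D_try, E_w_try = objective(w_try, alpha, beta)
            if np.isfinite(F_try) and F_try < F:
                wv, F, E_D, E_w = w_try, F_try, E_D_try, E_w_try
                mu = max(mu * cfg.mu_dec, 1e-20)
                accepted = True
                break
            mu *= cfg.mu_inc
        if not accepted:
            stop_reason = "max_mu"
            break
        F_accepted = F  # objective after the step, same (alpha, beta) as F_before

        # evidence update of the hyper-parameters (Foresee-Hagan recipe);
        # gamma = k - 2 alpha tr(H^-1) evaluated through the eigenvalues of
        # J'J, which stays finite when alpha -> 0 or J'J is rank-deficient
        if alpha == 0.0:
            gamma = float(k)
        else:
            s = np.clip(linalg.eigvalsh(JTJ), 0.0, None)
            gamma = float(np.sum(2.0 * beta * s / (2.0 * beta * s + 2.0 * alpha)))
        gamma = float(np.clip(gamma, 0.0, k))
        alpha = gamma / (2.0 * E_w) if E_w > 0 else 0.0
        beta = (N - gamma) / (2.0 * E_D) if E_D > 0 else 1e12
        F = beta * E_D + alpha * E_w
        history.append(
            dict(
                epoch=epoch,
                F_before=float(F_before),
                F_accepted=float(F_accepted),
                E_D=E_D,
                E_w=E_w,
                alpha=alpha,
                beta=beta,
                gamma=gamma,
                mu=mu,
                gradient=grad_norm,
            )
        )
    else:
        stop_reason = "max_epochs"

    w_fin = NarxWeights.from_vector(arch, wv)
    state = BayesRegState(
        alpha=alpha, beta=beta, E_D=E_D, E_w=E_w, gamma=gamma, mu=mu, epoch=epoch
    )
    report = TrainingReport(
        epochs_run=epoch,
        final_mse=E_D / N,
        final_gradient=grad_norm if np.isfinite(grad_norm) else 0.0,
        final_state=state,
        stop_reason=stop_reason,
        history=history,
        warnings=warnings,
    )
    if val_idx is not None and val_idx.size:
        r_all = full_residual(wv)
        report.mse_val = float(np.mean(r_all[val_idx - d] ** 2))
        if test_idx is not None and test_idx.size:
            report.mse_test = float(np.mean(r_all[test_idx - d] ** 2))
    return w_fin, report


def cyclic_train(
    w0: NarxWeights,
    u: np.ndarray,
    y: np.ndarray,
    cfg: TrainingConfig,
    stress_scale: float | None = None,
) -> tuple[NarxWeights, list[TrainingReport]]:
    """Repeated regularized training under refreshed noise and data division.

    Each cycle reshuffles the train/validation/test division, perturbs the
    targets with Gaussian noise at that cycle's magnitude, and warm-starts
    from the previous cycle's weights.  Noise injection plus reshuffling is
    a generalization device: the network never sees the identical target
    sequence twice.
    """
    mags = (
        np.asarray(cfg.noise_magnitudes, dtype=float)
        if cfg.noise_magnitudes is not None
        else default_noise_magnitudes(cfg.cycles, stress_scale)
    )
    if mags.size != cfg.cycles:
        raise ValueError("need one noise magnitude per cycle")
    w = w0
    reports: list[TrainingReport] = []
    n = np.asarray(u).size
    d = w0.arch.max_delay
    for cycle in range(cfg.cycles):
        subsets = _cycle_split(n, cfg, cycle, d)
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed), int(cycle), 1])
        )
        y_cycle = add_training_noise(y, float(mags[cycle]), noise_rng)
        w, rep = train_bayesian_regularization(
            w, u, y_cycle, cfg, subsets=subsets, _cycle=cycle
        )
        reports.append(rep)
    return w, reports


# ---------------------------------------------------------------------------
# weight checkpoints
# ---------------------------------------------------------------------------


def save_weights(w: NarxWeights, path: str | os.PathLike) -> None:
    """Plain-text checkpoint; numbers keep 17 significant digits."""
    buf = io.StringIO()
    buf.write("# esomech NARX weights v1\n")
    buf.write(f"n_hidden {w.arch.n_hidden}\n")
    buf.write("input_delays " + " ".join(map(str, w.arch.input_delays)) + "\n")
    buf.write("feedback_delays " + " ".join(map(str, w.arch.feedback_delays)) + "\n")
    for name, block in (
        ("IW", w.IW),
        ("LW_fb", w.LW_fb),
        ("b1", w.b1.reshape(1, -1)),
        ("LW_out", w.LW_out.reshape(1, -1)),
        ("b2", np.array([[w.b2]])),
    ):
        buf.write(name + "\n")
        for row in block:
            buf.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def load_weights(path: str | os.PathLike) -> NarxWeights:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    header: dict[str, list[int]] = {}
    i = 0
    while lines[i].split()[0] in ("n_hidden", "input_delays", "feedback_delays"):
        parts = lines[i].split()
        header[parts[0]] = [int(p) for p in parts[1:]]
        i += 1
    arch = NarxArchitecture(
        n_hidden=header["n_hidden"][0],
        input_delays=tuple(header["input_delays"]),
        feedback_delays=tuple(header["feedback_delays"]),
    )
    blocks: dict[str, list[list[float]]] = {}
    name = None
    for ln in lines[i:]:
        parts = ln.split()
        if parts[0] in ("IW", "LW_fb", "b1", "LW_out", "b2"):
            name = parts[0]
            blocks[name] = []
        else:
            blocks[name].append([float(p) for p in parts])
    return NarxWeights(
        arch=arch,
        IW=np.array(blocks["IW"]),
        LW_fb=np.array(blocks["LW_fb"]),
        b1=np.array(blocks["b1"]).ravel(),
        LW_out=np.array(blocks["LW_out"]).ravel(),
        b2=float(blocks["b2"][0][0]),
    )
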