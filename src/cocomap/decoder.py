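"""Sparse recovery of presynaptic weight vectors from (M, y).

Each observed neuron's incoming weight vector x is estimated from its trial
responses by L1-regularised regression

    min_x  lambda * ||x||_1 + 1/2 * ||y - M x||_2^2,

optionally subject to cell-type sign constraints x(E) >= 0, x(I) <= 0, or in
the basis-pursuit form  min ||x||_1  s.t.  ||y - M x||_2 <= epsilon.
Estimated matrices are thresholded relative to the strongest recovered
weight to declare connections, and presynaptic cell types can be inferred
from an unconstrained reconstruction and fed back as constraints.

Solvers: the unconstrained problem uses coordinate descent; the
sign-constrained problem is reduced to a positive lasso by flipping the sign
of inhibitory columns (z = s * x with s in {+1, -1} makes ||x||_1 linear on
z >= 0); basis pursuit with epsilon = 0 is the classic linear program, and
epsilon > 0 is solved by root-finding on lambda along the lasso Pareto
frontier, where the residual norm is monotone in lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .extraction import MeasurementSet
from .stimulation import StimulationMatrix

__all__ = [
    "DecoderConfig",
    "ReconstructionResult",
    "DecodeFailure",
    "solve_lasso",
    "solve_basis_pursuit",
    "solve_sign_constrained",
    "classify_cell_types_from_reconstruction",
    "threshold_weights",
    "siso_baseline",
    "reconstruct_network",
]


class DecodeFailure(RuntimeError):
    pass


@dataclass
class DecoderConfig:
    """Decoder settings.

    lam            sparsity/error trade-off of the L1 objective (base 0.25)
    epsilon        noise bound when using the basis-pursuit form
    rel_threshold  connection threshold as a fraction of the strongest
                   recovered weight (base 0.01)
    mode           "unconstrained" | "oracle_sign_constrained" |
                   "inferred_sign_constrained"
    form           "lasso" (penalised) or "basis_pursuit" (constrained)
    squared_loss   if False, use the unsquared-residual variant
                   lambda*||x||_1 + 1/2*||y - Mx||_2 of the penalised form
    per_cell_threshold  threshold each postsynaptic row against its own
                   maximum instead of the global maximum
    """

    lam: float = 0.25
    epsilon: float | None = None
    rel_threshold: float = 0.01
    mode: str = "unconstrained"
    form: str = "lasso"
    squared_loss: bool = True
    per_cell_threshold: bool = False

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not 0.0 < self.rel_threshold < 1.0:
            raise ValueError("rel_threshold must lie in (0, 1)")
        if self.mode not in (
            "unconstrained",
            "oracle_sign_constrained",
            "inferred_sign_constrained",
        ):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.form not in ("lasso", "basis_pursuit"):
            raise ValueError(f"unknown form {self.form!r}")


@dataclass
class ReconstructionResult:
    """Estimated weights, declared connections and per-neuron diagnostics."""

    x_hat: np.ndarray  # (n_obs, n_obs), [post, pre]
    adjacency: np.ndarray  # bool, same shape
    inferred_excitatory: np.ndarray | None  # (n_obs,) bool, or None
    diagnostics: dict = field(default_factory=dict)

    def export(self, directory) -> None:
        from pathlib import Path
        import json

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.x_hat).to_csv(d / "estimated_weights.csv", index=False)
        pd.DataFrame(self.adjacency.astype(int)).to_csv(d / "adjacency.csv", index=False)
        if self.inferred_excitatory is not None:
            pd.DataFrame(
                {
                    "id": np.arange(len(self.inferred_excitatory)),
                    "type": np.where(
                        self.inferred_excitatory, "excitatory", "inhibitory"
                    ),
                }
            ).to_csv(d / "inferred_labels.csv", index=False)
        (d / "diagnostics.json").write_text(json.dumps(self.diagnostics, default=str))


def _objective(M: np.ndarray, y: np.ndarray, x: np.ndarray, lam: float) -> float:
    r = y - M @ x
    return lam * np.abs(x).sum() + 0.5 * float(r @ r)


def _cd_lasso(M: np.ndarray, y: np.ndarray, lam: float, positive: bool) -> np.ndarray:
    """Coordinate-descent solve of lam*||x||_1 + 1/2*||y-Mx||^2 (+ x>=0)."""
    T = M.shape[0]
    if T == 0 or M.shape[1] == 0:
        return np.zeros(M.shape[1])
    model = Lasso(
        alpha=lam / T,  # scikit-learn scales the quadratic term by 1/T
        fit_intercept=False,
        positive=positive,
        max_iter=100_000,
        tol=1e-8,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(M, y)
        except ConvergenceWarning as exc:  # pragma: no cover - defensive
            raise DecodeFailure(f"lasso solver did not converge: {exc}") from exc
    return np.asarray(model.coef_, dtype=float)


def solve_lasso(M_sub: np.ndarray, y_sub: np.ndarray, lam: float) -> np.ndarray:
    """Minimise lambda*||x||_1 + 1/2*||y - Mx||_2^2 over unconstrained x."""
    M_sub = np.asarray(M_sub, dtype=float)
    y_sub = np.asarray(y_sub, dtype=float)
    if not np.any(y_sub):
        return np.zeros(M_sub.shape[1])
    return _cd_lasso(M_sub, y_sub, lam, positive=False)


def solve_unsquared_lasso(
    M_sub: np.ndarray, y_sub: np.ndarray, lam: float, max_iter: int = 50
) -> np.ndarray:
    """Variant with an unsquared residual norm: lam*||x||_1 + 1/2*||y-Mx||_2.

    Stationarity matches the squared form at an effective penalty
    lam' = lam * ||y - Mx||_2, so the solution is found by fixed-point
    iteration on lam'.
    """
    M_sub = np.asarray(M_sub, dtype=float)
    y_sub = np.asarray(y_sub, dtype=float)
    lam_eff = lam * max(np.linalg.norm(y_sub), 1e-12)
    x = np.zeros(M_sub.shape[1])
    for _ in range(max_iter):
        x_new = _cd_lasso(M_sub, y_sub, lam_eff, positive=False)
        r = np.linalg.norm(y_sub - M_sub @ x_new)
        new_lam = lam * max(r, 1e-12)
        if abs(new_lam - lam_eff) <= 1e-10 * lam_eff:
            return x_new
        lam_eff, x = new_lam, x_new
    return x


def solve_basis_pursuit(
    M_sub: np.ndarray, y_sub: np.ndarray, epsilon: float
) -> np.ndarray:
    """min ||x||_1 subject to ||y - Mx||_2 <= epsilon."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    M_sub = np.asarray(M_sub, dtype=float)
    y_sub = np.asarray(y_sub, dtype=float)
    T, N = M_sub.shape
    if np.linalg.norm(y_sub) <= epsilon:
        return np.zeros(N)  # x = 0 feasible, minimal norm
    if epsilon == 0.0:
        # LP: min 1'(p+q) s.t. M(p-q) = y, p,q >= 0
        res = linprog(
            c=np.ones(2 * N),
            A_eq=np.hstack([M_sub, -M_sub]),
            b_eq=y_sub,
            bounds=(0, None),
            method="highs",
        )
        if not res.success:
            raise DecodeFailure(f"equality basis pursuit infeasible: {res.message}")
        return res.x[:N] - res.x[N:]

    # Feasibility: the smallest attainable residual (lambda -> 0 limit).
    x_ls, *_ = np.linalg.lstsq(M_sub, y_sub, rcond=None)
    r_floor = np.linalg.norm(y_sub - M_sub @ x_ls)
    if epsilon < r_floor - 1e-8:
        raise DecodeFailure(
            f"epsilon={epsilon:.4g} below the residual floor {r_floor:.4g}"
        )

    def residual(lam: float) -> tuple[float, np.ndarray]:
        x = _cd_lasso(M_sub, y_sub, lam, positive=False)
        return float(np.linalg.norm(y_sub - M_sub @ x)), x

    # Bracket the Pareto root residual(lam) = epsilon, then bisect.
    lam_hi = float(np.max(np.abs(M_sub.T @ y_sub)))  # x = 0 above this
    lam_lo = 1e-10 * max(lam_hi, 1.0)
    r_lo, x_lo = residual(lam_lo)
    if r_lo > epsilon:  # already within tolerance of the floor
        return x_lo
    for _ in range(100):
        lam_mid = np.sqrt(lam_lo * lam_hi)
        r_mid, x_mid = residual(lam_mid)
        if abs(r_mid - epsilon) <= 1e-6 * max(epsilon, 1.0):
            return x_mid
        if r_mid > epsilon:
            lam_hi = lam_mid
        else:
            lam_lo = lam_mid
    _, x_final = residual(lam_lo)  # feasible side
    return x_final


def solve_sign_constrained(
    M_sub: np.ndarray,
    y_sub: np.ndarray,
    lam: float,
    e_idx: np.ndarray,
    i_idx: np.ndarray,
) -> np.ndarray:
    """Lasso objective subject to x(E) >= 0 and x(I) <= 0.

    Exactly reduced to a positive lasso: with s = +1 on E and -1 on I,
    z = s * x >= 0 and ||x||_1 = 1'z, so solving the positive lasso on
    M * diag(s) and mapping back is the constrained optimum.
    """
    M_sub = np.asarray(M_sub, dtype=float)
    y_sub = np.asarray(y_sub, dtype=float)
    N = M_sub.shape[1]
    e_idx = np.asarray(e_idx, dtype=int)
    i_idx = np.asarray(i_idx, dtype=int)
    marks = np.zeros(N, dtype=int)
    marks[e_idx] += 1
    marks[i_idx] += 1
    if not np.all(marks == 1):
        raise ValueError("e_idx and i_idx must partition the presynaptic index set")
    s = np.ones(N)
    s[i_idx] = -1.0
    z = _cd_lasso(M_sub * s, y_sub, lam, positive=True)
    return s * z


def classify_cell_types_from_reconstruction(x_hat: np.ndarray) -> np.ndarray:
    """Label each presynaptic cell by the sign of its summed outgoing weights.

    Column sums across postsynaptic cells weight strong connections more;
    zero-sum ties go to excitatory (the majority class).  Returns a boolean
    array, True = excitatory.
    """
    col_sums = np.asarray(x_hat, dtype=float).sum(axis=0)
    return col_sums >= 0.0


def threshold_weights(
    x_hat: np.ndarray, rel_threshold: float = 0.01, per_cell: bool = False
) -> np.ndarray:
    """Declare connections where |x_hat| exceeds rel_threshold times the
    strongest recovered weight (global by default, per postsynaptic row with
    ``per_cell``).  An all-zero matrix yields an empty adjacency."""
    ab = np.abs(np.asarray(x_hat, dtype=float))
    if per_cell:
        ref = ab.max(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(ref > 0, ab > rel_threshold * ref, False)
    ref = ab.max()
    if ref == 0:
        return np.zeros_like(ab, dtype=bool)
    return ab > rel_threshold * ref


def siso_baseline(
    measurements: MeasurementSet, M: StimulationMatrix
) -> np.ndarray:
    """Sequential one-cell-per-trial estimate: weight (i, j) is directly
    proportional to cell i's response on the trial where j alone was
    stimulated.  Requires M to be a permutation of identity rows covering
    every observed cell once."""
    entries = M.entries
    if not (
        entries.shape[0] == entries.shape[1]
        and np.all(entries.sum(axis=1) == 1)
        and np.all(entries.sum(axis=0) == 1)
    ):
        raise ValueError("SISO baseline requires one-hot rows covering each cell once")
    trial_of_cell = np.argmax(entries, axis=0)  # trial where cell j was stimulated
    x_hat = measurements.y[:, trial_of_cell].astype(float)
    np.fill_diagonal(x_hat, 0.0)
    return x_hat


def _solve_one(
    M_sub: np.ndarray,
    y_sub: np.ndarray,
    cfg: DecoderConfig,
    signs: tuple[np.ndarray, np.ndarray] | None,
) -> np.ndarray:
    if signs is not None:
        return solve_sign_constrained(M_sub, y_sub, cfg.lam, signs[0], signs[1])
    if cfg.form == "basis_pursuit":
        if cfg.epsilon is None:
            raise ValueError("basis_pursuit form requires epsilon")
        return solve_basis_pursuit(M_sub, y_sub, cfg.epsilon)
    if not cfg.squared_loss:
        return solve_unsquared_lasso(M_sub, y_sub, cfg.lam)
    return solve_lasso(M_sub, y_sub, cfg.lam)


def _decode_matrix(
    measurements: MeasurementSet,
    M: StimulationMatrix,
    cfg: DecoderConfig,
    is_excitatory: np.ndarray | None,
) -> tuple[np.ndarray, dict]:
    """Per-neuron solves assembled into the (post, pre) weight matrix."""
    N = measurements.n_obs
    T = measurements.n_trials
    entries = np.asarray(M.entries[:T], dtype=float)
    x_hat = np.zeros((N, N))
    failures: dict[int, str] = {}
    for n in range(N):
        rows = ~measurements.excluded[n]
        pre = np.concatenate([np.arange(n), np.arange(n + 1, N)])
        M_sub = entries[np.ix_(rows, pre)]
        y_sub = measurements.y[n, rows]
        signs = None
        if is_excitatory is not None:
            exc_pre = is_excitatory[pre]
            signs = (np.flatnonzero(exc_pre), np.flatnonzero(~exc_pre))
        try:
            x_hat[n, pre] = _solve_one(M_sub, y_sub, cfg, signs)
        except DecodeFailure as exc:
            failures[n] = str(exc)
    diag = {
        "mode": cfg.mode,
        "lam": cfg.lam,
        "n_failures": len(failures),
        "failures": failures,
    }
    return x_hat, diag


def reconstruct_network(
    measurements: MeasurementSet,
    M: StimulationMatrix,
    cfg: DecoderConfig | None = None,
    true_is_excitatory: np.ndarray | None = None,
) -> ReconstructionResult:
    """Full decode of every observed neuron's presynaptic weight vector.

    Modes:
      unconstrained              one L1 solve per neuron
      oracle_sign_constrained    sign constraints from the true cell types
                                 (requires ``true_is_excitatory`` over the
                                 observed cells)
      inferred_sign_constrained  unconstrained solve, classify presynaptic
                                 types from the result, then re-solve with
                                 the inferred constraints
    """
    cfg = cfg or DecoderConfig()
    inferred: np.ndarray | None = None
    if cfg.mode == "oracle_sign_constrained":
        if true_is_excitatory is None:
            raise ValueError("oracle mode requires the true cell types")
        x_hat, diag = _decode_matrix(measurements, M, cfg, np.asarray(true_is_excitatory, bool))
    elif cfg.mode == "inferred_sign_constrained":
        x0, diag0 = _decode_matrix(measurements, M, cfg, None)
        inferred = classify_cell_types_from_reconstruction(x0)
        x_hat, diag = _decode_matrix(measurements, M, cfg, inferred)
        diag["first_pass"] = diag0
    else:
        x_hat, diag = _decode_matrix(measurements, M, cfg, None)
        inferred = classify_cell_types_from_reconstruction(x_hat)
    adjacency = threshold_weights(x_hat, cfg.rel_threshold, per_cell=cfg.per_cell_threshold)
    return ReconstructionResult(
        x_hat=x_hat,
        adjacency=adjacency,
        inferred_excitatory=inferred,
        diagnostics=diag,
    )
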