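"""NAMFIS-style deconvolution of NOE restraints into conformer populations.

Given a pool of candidate conformers and a set of experimental interproton
distances, the method finds the population vector w on the probability
simplex that best reproduces the ensemble-averaged distances

    d_calc_j(w) = ( Σ_i w_i d_ij^-e )^(-1/e),   e = 6 by default,

by minimizing the tolerance-weighted sum of squared deviations
Σ_j λ_j (d_exp_j − d_calc_j)² with λ_j = 1/tolerance_j². The r⁻⁶ power mean
is the rigid-molecule NOE averaging limit (r⁻³ is available for cases with
fast internal motion). Optimization runs on the simplex through a softmax
reparameterization with analytic gradients and multiple deterministic
starts: the uniform distribution, a non-negative least-squares solution of
the linearized (r⁻⁶-space) problem, the best single-conformer vertices and
seeded random Dirichlet draws. Populations below a reporting floor are
zeroed, and the fit is repeated on the surviving support.

Stability is probed by a leave-one-restraint-out jackknife, and fitted
ensembles are summarized as fold-class population percentages (folded /
semifolded / extended).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .core import Ensemble, MoleculeTopology, NOERestraint
from .descriptors import FOLD_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "NamfisOptions",
    "NamfisResult",
    "noe_average_distance",
    "build_distance_matrix",
    "namfis_fit",
    "jackknife_restraints",
    "summarize_fold_populations",
]


def noe_average_distance(
    distances: Sequence[float], weights: Sequence[float], exponent: float = 6.0
) -> float:
    """Population-averaged NOE distance (Σᵢ wᵢ dᵢ⁻ᵉ)^(−1/e).

    Bounded between the minimum and maximum input distance and never above
    the weighted arithmetic mean (power-mean inequality); heavily biased
    toward short distances, as NOE intensities are.
    """
    d = np.asarray(distances, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.shape != w.shape:
        raise ValueError("distances and weights must have equal length")
    if np.any(d <= 0):
        raise ValueError("all distances must be positive")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be a probability simplex vector")
    if exponent <= 0:
        raise ValueError("averaging exponent must be positive")
    return float((w * d ** (-exponent)).sum() ** (-1.0 / exponent))


@dataclass
class DistanceMatrix:
    """Interproton distances: rows = restraints, columns = pool conformers."""

    values: np.ndarray
    restraint_ids: list[str]
    conformer_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("distance matrix must be 2D")
        if self.values.shape != (len(self.restraint_ids), len(self.conformer_ids)):
            raise ValueError("distance matrix shape inconsistent with id lists")
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("all interproton distances must be positive and finite")

    @property
    def n_restraints(self) -> int:
        return self.values.shape[0]

    @property
    def n_conformers(self) -> int:
        return self.values.shape[1]

    def drop_restraint(self, index: int) -> "DistanceMatrix":
        keep = [k for k in range(self.n_restraints) if k != index]
        return DistanceMatrix(
            values=self.values[keep],
            restraint_ids=[self.restraint_ids[k] for k in keep],
            conformer_ids=list(self.conformer_ids),
        )


def _resolve_proton(
    label: str,
    topology: MoleculeTopology,
    proton_groups: Optional[dict[str, Sequence[int]]],
) -> list[int]:
    """Map a restraint endpoint to one or more hydrogen atom indices."""
    if proton_groups and label in proton_groups:
        return [int(a) for a in proton_groups[label]]
    tag_map = {tag: idx for idx, tag in topology.proton_labels.items()}
    if label in tag_map:
        return [tag_map[label]]
    try:
        idx = int(label)
    except ValueError:
        raise KeyError(
            f"cannot resolve proton label {label!r}: not an atom index, "
            "a tagged proton, or a key of the supplied proton-group map"
        ) from None
    if not (0 <= idx < topology.n_atoms):
        raise KeyError(f"proton atom index {idx} out of range (0..{topology.n_atoms - 1})")
    return [idx]


def build_distance_matrix(
    ensemble: Ensemble,
    restraints: Sequence[NOERestraint],
    proton_groups: Optional[dict[str, Sequence[int]]] = None,
    exponent: float = 6.0,
) -> DistanceMatrix:
    """Per-conformer interproton distances for every restraint.

    Restraint endpoints may name atom indices, tagged protons, or groups of
    equivalent protons (e.g. a methyl); group–group distances are r⁻ᵉ
    averaged over all member pairs within each conformer.
    """
    topo = ensemble.topology
    groups_i: list[list[int]] = []
    groups_j: list[list[int]] = []
    for r in restraints:
        groups_i.append(_resolve_proton(str(r.proton_i), topo, proton_groups))
        groups_j.append(_resolve_proton(str(r.proton_j), topo, proton_groups))
    coords = ensemble.coordinates  # (C, N, 3)
    n_c = ensemble.n_conformers
    values = np.zeros((len(restraints), n_c))
    for k, (gi, gj) in enumerate(zip(groups_i, groups_j)):
        a = coords[:, gi, :]  # (C, |gi|, 3)
        b = coords[:, gj, :]
        d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)  # (C, |gi|, |gj|)
        if np.any(d <= 0):
            raise ValueError(
                f"restraint {restraints[k].proton_i}–{restraints[k].proton_j}: "
                "coincident protons give a zero distance"
            )
        values[k] = (d ** (-exponent)).mean(axis=(1, 2)) ** (-1.0 / exponent)
    ids = [f"{r.proton_i}-{r.proton_j}" for r in restraints]
    return DistanceMatrix(values=values, restraint_ids=ids, conformer_ids=ensemble.conformer_ids)


@dataclass(frozen=True)
class NamfisOptions:
    """Configuration of the population fit.

    ``exponent`` — averaging power (6 = rigid-limit NOE, 3 = motion-averaged);
    ``weighted`` — λⱼ = 1/tolⱼ² weighting (uniform when off);
    ``n_starts`` — number of optimizer starts beyond the deterministic ones;
    ``reporting_floor`` — populations below this fraction are zeroed and the
    fit repeated on the remaining support;
    ``seed`` — seeds the random starts; identical seed ⇒ identical result.
    """

    exponent: float = 6.0
    weighted: bool = True
    n_starts: int = 10
    reporting_floor: float = 0.005
    seed: int = 0
    max_iter: int = 2000
    gtol: float = 1e-12


@dataclass
class NamfisResult:
    """Fitted conformer populations and fit diagnostics."""

    populations: np.ndarray
    ssd: float
    residuals: np.ndarray
    conformer_ids: list[str]
    restraint_ids: list[str]
    selected: list[str] = field(default_factory=list)
    fold_class_populations: Optional[dict[str, float]] = None
    n_starts_converged: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.populations, dtype=float)
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("populations must lie on the probability simplex")
        self.populations = np.clip(p, 0.0, None)

    def to_dict(self) -> dict:
        return {
            "populations": {
                cid: float(p) for cid, p in zip(self.conformer_ids, self.populations)
            },
            "ssd": float(self.ssd),
            "residuals": {
                rid: float(r) for rid, r in zip(self.restraint_ids, self.residuals)
            },
            "selected": list(self.selected),
            "fold_class_populations": self.fold_class_populations,
        }


def _softmax(theta: np.ndarray) -> np.ndarray:
    t = theta - theta.max()
    e = np.exp(t)
    return e / e.sum()


def _objective_and_grad(
    theta: np.ndarray, a_pow: np.ndarray, d_exp: np.ndarray, lam: np.ndarray, exponent: float
) -> tuple[float, np.ndarray]:
    w = _softmax(theta)
    y = a_pow @ w  # Σ_i w_i d_ij^-e per restraint
    d_calc = y ** (-1.0 / exponent)
    resid = d_exp - d_calc
    f = float((lam * resid**2).sum())
    # ∂d_calc/∂w_i = (-1/e) y^(-1/e - 1) a_pow[:, i]
    coef = 2.0 * lam * resid * (1.0 / exponent) * y ** (-1.0 / exponent - 1.0)
    g_w = coef @ a_pow  # ∂f/∂w
    g_theta = w * (g_w - float(g_w @ w))
    return f, g_theta


def _fit_on_support(
    a_pow: np.ndarray,
    d_exp: np.ndarray,
    lam: np.ndarray,
    exponent: float,
    starts: list[np.ndarray],
    options: NamfisOptions,
) -> tuple[np.ndarray, float, int]:
    best_w: Optional[np.ndarray] = None
    best_f = np.inf
    n_ok = 0
    diagnostics = []
    for w0 in starts:
        theta0 = np.log(np.clip(w0, 1e-12, None))
        res = optimize.minimize(
            _objective_and_grad,
            theta0,
            args=(a_pow, d_exp, lam, exponent),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": options.max_iter, "ftol": 1e-16, "gtol": options.gtol},
        )
        diagnostics.append(res.message)
        if np.all(np.isfinite(res.x)):
            n_ok += 1
            f = float(res.fun)
            if f < best_f:
                best_f = f
                best_w = _softmax(res.x)
    if best_w is None:
        raise RuntimeError(
            "population fit failed to converge from any start; optimizer "
            f"messages: {diagnostics}"
        )
    return best_w, best_f, n_ok


def _objective_w(
    w: np.ndarray, a_pow: np.ndarray, d_exp: np.ndarray, lam: np.ndarray, exponent: float
) -> tuple[float, np.ndarray]:
    y = a_pow @ np.clip(w, 1e-300, None)
    d_calc = y ** (-1.0 / exponent)
    resid = d_exp - d_calc
    f = float((lam * resid**2).sum())
    coef = 2.0 * lam * resid * (1.0 / exponent) * y ** (-1.0 / exponent - 1.0)
    return f, coef @ a_pow


def _slsqp_polish(
    w0: np.ndarray,
    f0: float,
    a_pow: np.ndarray,
    d_exp: np.ndarray,
    lam: np.ndarray,
    exponent: float,
) -> tuple[np.ndarray, float]:
    """Sequential-quadratic polish directly on the simplex.

    The softmax parameterization cannot produce exact zeros and can stall on
    its plateaus; a constrained polish from the incumbent tightens the
    objective and sharpens boundary solutions. The incumbent is kept when
    the polish does not improve it.
    """
    n = len(w0)
    res = optimize.minimize(
        _objective_w,
        w0,
        args=(a_pow, d_exp, lam, exponent),
        jac=True,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[
            {
                "type": "eq",
                "fun": lambda w: w.sum() - 1.0,
                "jac": lambda w: np.ones(n),
            }
        ],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if np.all(np.isfinite(res.x)):
        w = np.clip(res.x, 0.0, None)
        s = w.sum()
        if s > 0:
            w = w / s
            f, _ = _objective_w(w, a_pow, d_exp, lam, exponent)
            if f < f0:
                return w, f
    return w0, f0


def _make_starts(
    a_pow: np.ndarray,
    d_exp: np.ndarray,
    lam: np.ndarray,
    exponent: float,
    options: NamfisOptions,
    n_conf: int,
) -> list[np.ndarray]:
    starts: list[np.ndarray] = [np.full(n_conf, 1.0 / n_conf)]
    # linearized start: match r^-e-space data by NNLS with a sum-to-one row
    y_exp = d_exp ** (-exponent)
    scale = np.sqrt(lam)
    rho = max(1.0, float((scale[:, None] * a_pow).max()))
    a_stack = np.vstack([scale[:, None] * a_pow, rho * np.ones((1, n_conf))])
    b_stack = np.concatenate([scale * y_exp, [rho]])
    try:
        w_nnls, _ = optimize.nnls(a_stack, b_stack)
        if w_nnls.sum() > 0:
            starts.append(w_nnls / w_nnls.sum())
    except Exception:  # pragma: no cover - nnls failure is benign, other starts remain
        pass
    # best single-conformer vertices (softened for the softmax parameterization)
    vertex_obj = (lam[:, None] * (d_exp[:, None] - a_pow ** (-1.0 / exponent)) ** 2).sum(axis=0)
    for i in np.argsort(vertex_obj)[:2]:
        v = np.full(n_conf, 1e-6)
        v[i] = 1.0
        starts.append(v / v.sum())
    rng = np.random.default_rng(options.seed)
    while len(starts) < max(options.n_starts, len(starts)):
        starts.append(rng.dirichlet(np.ones(n_conf)))
    return starts


def namfis_fit(
    matrix: DistanceMatrix,
    restraints: Sequence[NOERestraint],
    options: NamfisOptions = NamfisOptions(),
) -> NamfisResult:
    """Fit conformer populations to NOE distances on the probability simplex.

    Returns the best of all optimizer starts; populations below the
    reporting floor are zeroed and the objective re-minimized on the
    surviving support. The reported ``ssd`` is the (tolerance-weighted)
    sum of squared distance deviations at the solution, and ``residuals``
    are d_exp − d_calc per restraint.
    """
    if len(restraints) != matrix.n_restraints:
        raise ValueError("restraint list does not match distance-matrix rows")
    if matrix.n_conformers < 1 or matrix.n_restraints < 1:
        raise ValueError("need at least one conformer and one restraint")
    d_exp = np.array([r.d_exp for r in restraints], dtype=float)
    if options.weighted:
        tol = np.array([max(r.tolerance, 1e-6) for r in restraints])
        lam = 1.0 / tol**2
    else:
        lam = np.ones_like(d_exp)
    a_pow = matrix.values ** (-options.exponent)
    n_conf = matrix.n_conformers

    if n_conf > 1 and np.allclose(
        matrix.values, matrix.values[:, [0]], rtol=1e-12, atol=1e-12
    ):
        warnings.warn(
            "all pool conformers present identical restraint distances; "
            "populations are not identifiable",
            stacklevel=2,
        )

    if n_conf == 1:
        w = np.array([1.0])
        y = a_pow @ w
        d_calc = y ** (-1.0 / options.exponent)
        resid = d_exp - d_calc
        return NamfisResult(
            populations=w,
            ssd=float((lam * resid**2).sum()),
            residuals=resid,
            conformer_ids=list(matrix.conformer_ids),
            restraint_ids=list(matrix.restraint_ids),
            selected=list(matrix.conformer_ids),
            n_starts_converged=1,
        )

    starts = _make_starts(a_pow, d_exp, lam, options.exponent, options, n_conf)
    w, f, n_ok = _fit_on_support(a_pow, d_exp, lam, options.exponent, starts, options)
    w, f = _slsqp_polish(w, f, a_pow, d_exp, lam, options.exponent)

    # reporting floor: zero trace populations, renormalize, refit on support
    support = np.nonzero(w >= options.reporting_floor)[0]
    if 0 < support.size < n_conf:
        w_sub = w[support] / w[support].sum()
        sub_starts = [w_sub, np.full(support.size, 1.0 / support.size)]
        w_ref, f_ref, _ = _fit_on_support(
            a_pow[:, support], d_exp, lam, options.exponent, sub_starts, options
        )
        w_ref, f_ref = _slsqp_polish(
            w_ref, f_ref, a_pow[:, support], d_exp, lam, options.exponent
        )
        # the floor is a reporting device, not a constraint: keep the floored
        # refit only when it does not degrade the fit, so the reported
        # objective never increases over the multi-start optimum
        if f_ref <= f + max(1e-12, 1e-9 * abs(f)):
            w_full = np.zeros(n_conf)
            w_full[support] = w_ref
            w, f = w_full, f_ref
        else:
            logger.info(
                "reporting-floor refit degraded the objective (%.3g -> %.3g); "
                "keeping the unfloored populations",
                f,
                f_ref,
            )
    w = np.where(w < 1e-15, 0.0, w)
    w = w / w.sum()

    y = a_pow @ w
    d_calc = y ** (-1.0 / options.exponent)
    resid = d_exp - d_calc
    selected = [
        matrix.conformer_ids[i] for i in range(n_conf) if w[i] >= options.reporting_floor
    ]
    return NamfisResult(
        populations=w,
        ssd=float((lam * resid**2).sum()),
        residuals=resid,
        conformer_ids=list(matrix.conformer_ids),
        restraint_ids=list(matrix.restraint_ids),
        selected=selected,
        n_starts_converged=n_ok,
    )


def jackknife_restraints(
    matrix: DistanceMatrix,
    restraints: Sequence[NOERestraint],
    options: NamfisOptions = NamfisOptions(),
) -> dict:
    """Leave-one-restraint-out stability analysis.

    Refits the populations with each restraint excluded in turn and reports
    the min/max population per conformer across the folds, plus each fold's
    ssd. Folds whose fit fails are skipped with a warning.
    """
    if matrix.n_restraints < 2:
        raise ValueError("jackknife needs at least two restraints")
    pops = []
    fold_ssd = {}
    for k in range(matrix.n_restraints):
        sub_matrix = matrix.drop_restraint(k)
        sub_restraints = [r for i, r in enumerate(restraints) if i != k]
        try:
            res = namfis_fit(sub_matrix, sub_restraints, options)
        except Exception as exc:
            warnings.warn(
                f"jackknife fold excluding restraint {matrix.restraint_ids[k]!r} "
                f"failed: {exc}",
                stacklevel=2,
            )
            continue
        pops.append(res.populations)
        fold_ssd[matrix.restraint_ids[k]] = res.ssd
    if not pops:
        raise RuntimeError("every jackknife fold failed")
    stacked = np.vstack(pops)
    return {
        "population_min": {
            cid: float(v) for cid, v in zip(matrix.conformer_ids, stacked.min(axis=0))
        },
        "population_max": {
            cid: float(v) for cid, v in zip(matrix.conformer_ids, stacked.max(axis=0))
        },
        "fold_ssd": fold_ssd,
        "n_folds": len(pops),
    }


def summarize_fold_populations(
    result: NamfisResult, fold_classes: Sequence[str]
) -> dict[str, float]:
    """Aggregate fitted populations into fold-class percentages.

    ``fold_classes`` gives one class (folded / semifolded / extended) per
    pool conformer, in pool order. Percentages sum to 100.
    """
    if len(fold_classes) != len(result.populations):
        raise ValueError(
            f"need one fold class per pool conformer "
            f"({len(result.populations)}), got {len(fold_classes)}"
        )
    for c in fold_classes:
        if c not in FOLD_CLASSES:
            raise ValueError(f"unknown fold class {c!r}")
    total = float(result.populations.sum())
    if total <= 0:
        raise ValueError("result carries no population mass to summarize")
    out = {c: 0.0 for c in FOLD_CLASSES}
    for c, p in zip(fold_classes, result.populations):
        out[c] += 100.0 * float(p) / total
    return out
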