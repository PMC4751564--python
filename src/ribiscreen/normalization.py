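"""Plate normalization of duplex qPCR ratios via a two-population mixture.

Each well yields an F-J value (reporter Ct minus housekeeping Ct). On a
library plate most strains repress the reporter normally and cluster in one
population, while repression-defective strains form a low-F-J outlier
population (more reporter transcript = lower reporter Ct = lower F-J). A
two-component 1-D Gaussian mixture, fitted by EM, identifies the majority
population; its mean is subtracted from the whole plate and the sign is
flipped, so the plate's normal strains sit at 0 and defects come out as
positive log2 reporter/housekeeping ratios. This cancels the 0.3-0.6 cycle
run-to-run offsets seen on the reporter channel.

Re-arrayed plates that are mostly hits violate the majority assumption; for
those, centering uses designated center-peak control wells instead
(:func:`normalize_with_controls`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .plate_io import WellRecord

MIN_PLATE_WELLS = 8
MIN_CONTROL_WELLS = 4


@dataclass(frozen=True)
class FJValue:
    """Reporter-minus-housekeeping Ct difference for one well."""

    strain_id: str
    plate_id: str
    condition: str
    fj: float
    well: str = ""
    role: str = "library"


@dataclass(frozen=True)
class NormalizedRatio:
    """Plate-centered, sign-flipped log2 reporter/housekeeping expression.

    Higher values mean more reporter transcript relative to the plate's
    majority (defect-free) population.
    """

    strain_id: str
    plate_id: str
    condition: str
    log2_ratio: float
    well: str = ""
    role: str = "library"


@dataclass(frozen=True)
class MixtureFit:
    """Converged two-component 1-D Gaussian mixture for one plate."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float
    n_iterations: int
    converged: bool
    majority_component: int
    degenerate: bool
    log_likelihood_path: tuple[float, ...] = field(default=(), repr=False)

    def to_dict(self) -> dict:
        return {
            "weights": list(self.weights),
            "means": list(self.means),
            "sds": list(self.sds),
            "log_likelihood": self.log_likelihood,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "majority_component": self.majority_component,
            "degenerate": self.degenerate,
        }


def compute_fj(well: WellRecord) -> FJValue:
    """F-J value of a filtered well: reporter Ct minus housekeeping Ct."""
    if well.ct_fam is None or well.ct_joe is None:
        raise ValueError(
            f"well {well.plate_id}/{well.well} is missing a channel; filter wells first"
        )
    return FJValue(
        strain_id=well.strain_id,
        plate_id=well.plate_id,
        condition=well.condition,
        fj=well.ct_fam - well.ct_joe,
        well=well.well,
        role=well.role,
    )


def _log_mixture_density(x: np.ndarray, w, mu, var) -> np.ndarray:
    """Per-point log density matrix (n, 2) including component log weights."""
    return (
        np.log(w)
        - 0.5 * math.log(2.0 * math.pi)
        - 0.5 * np.log(var)
        - 0.5 * (x[:, None] - mu) ** 2 / var
    )


def _em_run(x, mu0, sd0, w0, variance_floor, max_iter, tol):
    w = np.asarray(w0, float).copy()
    mu = np.asarray(mu0, float).copy()
    var = np.maximum(np.asarray(sd0, float) ** 2, variance_floor)
    path: list[float] = []
    ll_prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logp = _log_mixture_density(x, w, mu, var)
        norm = np.logaddexp(logp[:, 0], logp[:, 1])
        ll = float(norm.sum())
        path.append(ll)
        resp = np.exp(logp - norm[:, None])
        if ll - ll_prev < tol and n_iter > 1:
            converged = True
            break
        ll_prev = ll
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / nk.sum()
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        # clamping to the floor is the constrained M-step maximizer, so the
        # log-likelihood stays monotone even when a component collapses
        var = np.maximum(var, variance_floor)
    return w, mu, np.sqrt(var), path[-1], n_iter, converged, path


def fit_mixture_em(
    values: Iterable[float],
    k: int = 2,
    *,
    variance_floor: float = 1e-3,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int | None = None,
    n_restarts: int = 0,
    separation_threshold: float = 0.5,
    max_minority_weight: float = 0.4,
) -> MixtureFit:
    """Fit a two-component 1-D Gaussian mixture by EM.

    Initialization is deterministic (quantile-based starts plus a
    low-decile/remainder split); ``seed`` only matters when extra random
    restarts are requested via ``n_restarts``. The fit is flagged
    ``degenerate`` when the components are closer than
    ``separation_threshold`` log2 units or the minority weight exceeds
    ``max_minority_weight`` -- i.e. when there is no credible outlier
    population to separate.
    """
    if k != 2:
        raise ValueError("only two-component mixtures are supported")
    x = np.asarray(list(values), dtype=float)
    if x.size < MIN_PLATE_WELLS:
        raise ValueError(f"need at least {MIN_PLATE_WELLS} values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")

    if np.ptp(x) == 0.0:
        # all values identical: a single effective component at that value
        sd = math.sqrt(variance_floor)
        ll = float(np.sum(stats.norm.logpdf(x, loc=x[0], scale=sd)))
        return MixtureFit(
            weights=(1.0, 0.0),
            means=(float(x[0]), float(x[0])),
            sds=(sd, sd),
            log_likelihood=ll,
            n_iterations=0,
            converged=True,
            majority_component=0,
            degenerate=True,
            log_likelihood_path=(ll,),
        )

    sd0 = max(float(np.std(x)), math.sqrt(variance_floor))
    sd_floor = math.sqrt(variance_floor)
    q = np.quantile(x, [0.05, 0.25, 0.75, 0.95])
    inits = [
        ((q[1], q[2]), (sd0, sd0), (0.5, 0.5)),
        ((q[0], q[3]), (sd0, sd0), (0.5, 0.5)),
    ]
    # ordered-split starts: candidate low/high partitions of the sorted data,
    # each with its own per-side mean, sd, and weight
    xs = np.sort(x)
    n = x.size
    for frac in (0.05, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95):
        k = min(max(int(round(frac * n)), 1), n - 1)
        lo, hi = xs[:k], xs[k:]
        inits.append(
            (
                (float(lo.mean()), float(hi.mean())),
                (max(float(lo.std()), sd_floor), max(float(hi.std()), sd_floor)),
                (k / n, 1 - k / n),
            )
        )
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            mu_r = rng.choice(x, size=2, replace=False)
            inits.append((tuple(mu_r), (sd0, sd0), (0.5, 0.5)))

    # short EM runs from every start, then run only the best to convergence
    short_iter = min(20, max_iter)
    best = None
    for mu0, s0, w0 in inits:
        run = _em_run(x, mu0, s0, w0, variance_floor, short_iter, tol)
        if best is None or run[3] > best[3]:
            best = run
    w, mu, sd, ll, n_iter, converged, path = best
    if not converged and max_iter > short_iter:
        w, mu, sd, ll, n_cont, converged, cont_path = _em_run(
            x, mu, sd, w, variance_floor, max_iter - short_iter, tol
        )
        n_iter += n_cont - 1
        path = list(path) + list(cont_path[1:])

    if abs(w[0] - w[1]) < 1e-12:
        majority = int(np.argmax(mu))  # tie: defects lower F-J, so majority is higher
    else:
        majority = int(np.argmax(w))
    degenerate = bool(
        abs(mu[0] - mu[1]) < separation_threshold or float(np.min(w)) > max_minority_weight
    )
    return MixtureFit(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        log_likelihood=float(ll),
        n_iterations=int(n_iter),
        converged=bool(converged),
        majority_component=majority,
        degenerate=degenerate,
        log_likelihood_path=tuple(path),
    )


def responsibilities(values: Iterable[float], fit: MixtureFit) -> np.ndarray:
    """Posterior component membership probabilities, shape (n, 2)."""
    x = np.asarray(list(values), dtype=float)
    w = np.maximum(np.asarray(fit.weights), 1e-300)
    logp = _log_mixture_density(x, w, np.asarray(fit.means), np.asarray(fit.sds) ** 2)
    norm = np.logaddexp(logp[:, 0], logp[:, 1])
    return np.exp(logp - norm[:, None])


def _normalize(fj_values: Sequence[FJValue], center: float) -> list[NormalizedRatio]:
    return [
        NormalizedRatio(
            strain_id=f.strain_id,
            plate_id=f.plate_id,
            condition=f.condition,
            log2_ratio=-(f.fj - center),
            well=f.well,
            role=f.role,
        )
        for f in fj_values
    ]


def normalize_plate(
    fj_values: Sequence[FJValue],
    *,
    trim: float = 0.2,
    **em_kwargs,
) -> tuple[list[NormalizedRatio], MixtureFit]:
    """Mixture-normalize one plate (one condition).

    The mean F-J of wells assigned to the majority component (posterior
    responsibility >= 0.5) is subtracted from every well, then all values are
    multiplied by -1. When the mixture is degenerate -- no separable outlier
    population -- the plate's ``trim``-trimmed mean is subtracted instead.
    """
    if len(fj_values) < MIN_PLATE_WELLS:
        raise ValueError(
            f"plate has {len(fj_values)} wells; need at least {MIN_PLATE_WELLS}"
        )
    x = np.array([f.fj for f in fj_values], dtype=float)
    fit = fit_mixture_em(x, **em_kwargs)
    if fit.degenerate:
        center = float(stats.trim_mean(x, trim))
    else:
        member = responsibilities(x, fit)[:, fit.majority_component] >= 0.5
        if not member.any():  # pathological fit; fall back to robust centering
            center = float(stats.trim_mean(x, trim))
        else:
            center = float(x[member].mean())
    return _normalize(fj_values, center), fit


def normalize_with_controls(
    fj_values: Sequence[FJValue],
    control_strain_ids: Iterable[str],
) -> list[NormalizedRatio]:
    """Center a plate on designated control wells instead of the mixture.

    Used for re-arrayed plates where most wells are hits, so the mixture's
    majority assumption fails; the mean F-J of the control wells is set to
    zero and the sign is flipped.
    """
    controls = set(control_strain_ids)
    ctrl = [f.fj for f in fj_values if f.strain_id in controls]
    if len(ctrl) < MIN_CONTROL_WELLS:
        raise ValueError(
            f"found {len(ctrl)} control wells; need at least {MIN_CONTROL_WELLS}"
        )
    return _normalize(fj_values, float(np.mean(ctrl)))


def normalize_screen(
    wells: Sequence[WellRecord],
    *,
    method: str = "mixture",
    control_strain_ids: Iterable[str] | None = None,
    **kwargs,
) -> tuple[list[NormalizedRatio], dict[tuple[str, str], MixtureFit]]:
    """Normalize every (plate, condition) group of a filtered well set.

    Returns the pooled ratios plus per-plate mixture diagnostics (empty for
    the control-based method).
    """
    groups: dict[tuple[str, str], list[FJValue]] = {}
    for w in wells:
        groups.setdefault((w.plate_id, w.condition), []).append(compute_fj(w))
    ratios: list[NormalizedRatio] = []
    fits: dict[tuple[str, str], MixtureFit] = {}
    for key in sorted(groups):
        if method == "mixture":
            r, fit = normalize_plate(groups[key], **kwargs)
            fits[key] = fit
        elif method == "controls":
            if control_strain_ids is None:
                raise ValueError("control_strain_ids required for method='controls'")
            r = normalize_with_controls(groups[key], control_strain_ids)
        else:
            raise ValueError(f"unknown method {method!r}")
        ratios.extend(r)
    return ratios, fits


def strain_values(
    ratios: Iterable[NormalizedRatio], roles: tuple[str, ...] = ("library",)
) -> dict[str, float]:
    """Collapse normalized ratios to one value per strain (mean over wells).

    Strains measured on duplicate-run plates are combined by arithmetic
    mean; filler and control wells are excluded by default via ``roles``.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for r in ratios:
        if r.role not in roles:
            continue
        sums[r.strain_id] = sums.get(r.strain_id, 0.0) + r.log2_ratio
        counts[r.strain_id] = counts.get(r.strain_id, 0) + 1
    return {s: sums[s] / counts[s] for s in sums}
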