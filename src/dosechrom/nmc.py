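"""TF-nucleosome competition (nucleosome-mediated cooperativity) model.

A regulatory element is modeled as a stretch of DNA that is either wrapped in
a nucleosome or open, carrying ``n`` TF binding sites.  Three dimensionless
parameters govern the system: ``L``, the nucleosome/open equilibrium constant
in the absence of TF; ``c``, the fold-suppression of TF binding on nucleosomal
DNA (c=0 forbids binding in the wrapped state, c=1 means the nucleosome is
invisible to the TF); and the effective TF concentration ``alpha = [TF]/K_D``
per site.  Accessibility is one minus nucleosome occupancy:

    Acc = Z_open / (Z_open + Z_nuc)
    Z_open = prod_i (1 + alpha/KD_i)
    Z_nuc  = L * prod_i (1 + c*alpha/KD_i)

Because TF binding stabilizes the open state multiplicatively across sites,
multiple sites competing with the same nucleosome acquire emergent (nucleosome
mediated) cooperativity without any protein-protein interaction.

The module provides the forward model, theoretical ED50 of accessibility
titration curves, the crossover K_D ratio at which a second (weaker) site
switches from buffering to sensitizing, and least-squares fitting of the
model to empirical normalized dose-response curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.special import expit

__all__ = [
    "SiteSet",
    "NMCParams",
    "DoseCurve",
    "NMCFit",
    "NMCSummary",
    "accessibility",
    "theoretical_ed50",
    "crossover_ratio",
    "empirical_curve",
    "fit_nmc",
    "fit_nmc_scan",
    "select_n",
    "summarize_nmc",
]

# acceptance contract on fits: mse <= MSE_ACCEPT and c >= 0
MSE_ACCEPT = 1e-3


@dataclass(frozen=True)
class SiteSet:
    """Binding sites of a regulatory element, as dissociation constants.

    ``kds[i]`` with multiplicity ``counts[i]``; the grouped high/low-affinity
    form (n_ha sites at KD_HA, n_la sites at KD_LA = r*KD_HA) expands
    losslessly into this representation.
    """

    kds: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.kds) != len(self.counts):
            raise ValueError("kds and counts must have equal length")
        if any(k <= 0 for k in self.kds):
            raise ValueError("all dissociation constants must be positive")
        if any(n < 0 for n in self.counts):
            raise ValueError("site multiplicities must be nonnegative")

    @classmethod
    def explicit(cls, kds: Sequence[float]) -> "SiteSet":
        return cls(kds=tuple(float(k) for k in kds), counts=(1,) * len(kds))

    @classmethod
    def grouped(
        cls,
        n_ha: int,
        kd_ha: float = 1.0,
        n_la: int = 0,
        r: float = 1.0,
    ) -> "SiteSet":
        """High/low-affinity grouped form; ``r = KD_LA / KD_HA >= 1``."""
        if r < 1:
            raise ValueError("K_D ratio r must be >= 1 (low-affinity site is weaker)")
        if n_la > 0:
            return cls(kds=(float(kd_ha), float(kd_ha) * float(r)), counts=(n_ha, n_la))
        return cls(kds=(float(kd_ha),), counts=(n_ha,))

    @property
    def explicit_kds(self) -> tuple[float, ...]:
        out: list[float] = []
        for k, n in zip(self.kds, self.counts):
            out.extend([k] * n)
        return tuple(out)

    @property
    def n_sites(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class NMCParams:
    """Nucleosome model constants: L (nucleosome/open equilibrium) and c."""

    L: float = 1e3
    c: float = 0.01

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must lie in [0, 1]")


@dataclass
class DoseCurve:
    """A normalized response curve on a dosage (or concentration) grid."""

    grid: np.ndarray
    response: np.ndarray
    curve_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.grid.shape != self.response.shape:
            raise ValueError("grid and response must have the same shape")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")


@dataclass
class NMCFit:
    """Fitted competition parameters for one curve under one site structure."""

    model: str  # e.g. "nHA=3" or "nHA=3,nLA=1"
    n_ha: int
    n_la: int
    c: float
    a100: float
    r: float
    mse: float
    converged: bool
    curve_id: str = ""

    @property
    def accepted(self) -> bool:
        return self.converged and self.mse <= MSE_ACCEPT and self.c >= 0


@dataclass
class NMCSummary:
    """Per-model-label summary over accepted fits."""

    model: str
    n_total: int
    n_accepted: int
    median_c: float = field(default=math.nan)
    median_r: float = field(default=math.nan)


def _log_weights(alpha, sites: SiteSet, params: NMCParams):
    """Return (log Z_open, log Z_nuc) for scalar or array alpha."""
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0):
        raise ValueError("alpha must be nonnegative")
    log_open = np.zeros_like(a)
    log_nuc = np.full_like(a, math.log(params.L))
    for kd, n in zip(sites.kds, sites.counts):
        log_open = log_open + n * np.log1p(a / kd)
        log_nuc = log_nuc + n * np.log1p(params.c * a / kd)
    return log_open, log_nuc


def accessibility(alpha, sites: SiteSet, params: NMCParams):
    """Accessibility Acc = Z_open/(Z_open+Z_nuc), computed in log space.

    Accepts a scalar or array ``alpha`` (concentration in units of KD when
    site KDs are 1).  At alpha=0, Acc = 1/(1+L); at saturation with n
    identical sites, Acc -> 1/(1 + L*c^n).
    """
    log_open, log_nuc = _log_weights(alpha, sites, params)
    # Acc = 1 / (1 + exp(log_nuc - log_open)); stable for both tails
    out = 1.0 / (1.0 + np.exp(np.clip(log_nuc - log_open, -700, 700)))
    if np.isscalar(alpha) or np.ndim(alpha) == 0:
        return float(out)
    return out


def theoretical_ed50(
    sites: SiteSet,
    params: NMCParams,
    alpha_range: tuple[float, float] = (1e-5, 1e5),
    rtol: float = 1e-6,
) -> float:
    """Concentration at half of the accessibility rise over ``alpha_range``.

    Solves Acc(alpha*) = Acc(0) + 0.5*(Acc_top - Acc(0)) where Acc_top is the
    accessibility at the top of the titration range, by log-grid bracketing
    followed by bisection.  Raises ValueError for flat curves (c=1, or no
    sites), which have no half-rise point.
    """
    lo, hi = alpha_range
    acc0 = accessibility(0.0, sites, params)
    acc_top = accessibility(hi, sites, params)
    rise = acc_top - acc0
    if rise <= 1e-12:
        raise ValueError("no half-rise point: accessibility curve is flat")
    target = acc0 + 0.5 * rise

    grid = np.logspace(math.log10(lo), math.log10(hi), 400)
    vals = accessibility(grid, sites, params) - target
    idx = np.nonzero(vals >= 0)[0]
    if idx.size == 0:
        raise ValueError("half-rise point not bracketed within alpha_range")
    i = int(idx[0])
    if i == 0:
        return float(grid[0])
    f = lambda x: accessibility(x, sites, params) - target
    return float(brentq(f, grid[i - 1], grid[i], rtol=rtol))


def crossover_ratio(
    params: NMCParams,
    r_range: tuple[float, float] = (1.0, 1e4),
    kd_ha: float = 1.0,
    alpha_range: tuple[float, float] = (1e-5, 1e5),
    n_grid: int = 240,
) -> float | None:
    """Smallest K_D ratio at which a second site raises the theoretical ED50.

    A single high-affinity site (KD = kd_ha) sets the reference ED50.  Adding
    a second site with KD = r*kd_ha buffers the response (lower ED50) at small
    r; under TF-nucleosome competition (c > 0) a sufficiently weak second site
    instead sensitizes (higher ED50).  Returns the crossover ratio r*, or None
    when no finite second site raises the ED50 within ``r_range`` (the c=0
    regime, where any second site is buffering).
    """
    single = SiteSet.explicit([kd_ha])
    ed50_single = theoretical_ed50(single, params, alpha_range)

    def excess(r: float) -> float:
        two = SiteSet.explicit([kd_ha, r * kd_ha])
        return theoretical_ed50(two, params, alpha_range) - ed50_single

    grid = np.logspace(math.log10(r_range[0]), math.log10(r_range[1]), n_grid)
    vals = np.array([excess(r) for r in grid])
    idx = np.nonzero(vals > 0)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(grid[0])
    return float(brentq(excess, grid[i - 1], grid[i], rtol=1e-6))


def empirical_curve(fit, n_points: int = 101) -> DoseCurve:
    """Normalized Hill response curve of a fitted RE on a 0..100% dosage grid.

    response(d) = (d^h/(d^h+e^h)) / (100^h/(100^h+e^h)), so response(0)=0 and
    response(100)=1 regardless of (e, h).  ``fit`` is any object with ``e``
    and ``h`` attributes (a HillFit) and optionally ``re_id``.
    """
    e, h = float(fit.e), float(fit.h)
    d = np.linspace(0.0, 100.0, n_points)
    raw = _hill_logistic(d, e, h)
    resp = raw / _hill_logistic(100.0, e, h)
    return DoseCurve(grid=d, response=resp, curve_id=getattr(fit, "re_id", ""))


def _hill_logistic(d, e, h):
    """d^h/(d^h+e^h) computed as a logistic in log-dose (overflow-safe)."""
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        out = expit(h * (np.log(d) - math.log(e)))
    return np.where(d == 0, 0.0, out)


def nmc_response(
    dosage,
    c: float,
    a100: float,
    r: float = 1.0,
    n_ha: int = 3,
    n_la: int = 0,
    L: float = 1e3,
):
    """Model dose-response: normalized accessibility rise at alpha(d)=d/100*a100.

    The dosage->concentration map is linear with the constant absorbed into
    a100 = alpha(100%)/KD_HA; only ratios are identifiable from curve shape.
    Returns [Acc(alpha(d)) - Acc(0)] / [Acc(alpha(100)) - Acc(0)].
    """
    sites = SiteSet.grouped(n_ha=n_ha, kd_ha=1.0, n_la=n_la, r=r)
    params = NMCParams(L=L, c=c)
    d = np.asarray(dosage, dtype=float)
    alpha = d / 100.0 * a100
    acc = accessibility(alpha, sites, params)
    acc0 = accessibility(0.0, sites, params)
    acc100 = accessibility(a100, sites, params)
    denom = acc100 - acc0
    if denom <= 1e-300:
        return np.zeros_like(d)
    return (acc - acc0) / denom


# multi-start grid: coarse decades around plausible competition strengths
_STARTS_C = (0.001, 0.01, 0.1)
_STARTS_A100 = (3.0, 30.0, 300.0)
_STARTS_R = (3.0, 30.0, 300.0)


def fit_nmc(
    curve: DoseCurve,
    n_ha: int,
    n_la: int = 0,
    L: float = 1e3,
) -> NMCFit:
    """Least-squares fit of the competition model to a normalized dose curve.

    Free parameters: (c, a100) for high-affinity-only structures, plus the
    K_D ratio r when n_la > 0.  Bounds c in [0,1], a100 in (0,1e6],
    r in [1,1e6]; a100 and r are optimized on log10 scale.  Multi-start over
    a coarse grid; best mean-squared-error wins.  A fit is accepted when
    mse <= 0.001 and c >= 0.
    """
    if curve.response[np.argmax(curve.grid)] < 0:
        raise ValueError("curve must be normalized with response(100) ~ 1")
    mixed = n_la > 0
    d, y = curve.grid, curve.response
    label = f"nHA={n_ha}" + (f",nLA={n_la}" if mixed else "")

    def resid(theta):
        c = theta[0]
        a100 = 10.0 ** theta[1]
        r = 10.0 ** theta[2] if mixed else 1.0
        return nmc_response(d, c, a100, r, n_ha=n_ha, n_la=n_la, L=L) - y

    lb = [0.0, -6.0] + ([0.0] if mixed else [])
    ub = [1.0, 6.0] + ([6.0] if mixed else [])

    best = None
    starts = [
        [c0, math.log10(a0)] + ([math.log10(r0)] if mixed else [])
        for c0 in _STARTS_C
        for a0 in _STARTS_A100
        for r0 in (_STARTS_R if mixed else (1.0,))
    ]
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        mse = float(np.mean(sol.fun**2))
        if best is None or mse < best[0]:
            best = (mse, sol)
    if best is None:
        return NMCFit(label, n_ha, n_la, math.nan, math.nan, math.nan,
                      math.inf, converged=False, curve_id=curve.curve_id)
    mse, sol = best
    c = float(sol.x[0])
    a100 = float(10.0 ** sol.x[1])
    r = float(10.0 ** sol.x[2]) if mixed else 1.0
    return NMCFit(label, n_ha, n_la, c, a100, r, mse, converged=True,
                  curve_id=curve.curve_id)


def fit_nmc_scan(
    curve: DoseCurve,
    n_ha_values: Sequence[int] = range(1, 8),
    n_la: int = 0,
    L: float = 1e3,
) -> list[NMCFit]:
    """Fit one curve at each candidate number of high-affinity sites."""
    return [fit_nmc(curve, n_ha=n, n_la=n_la, L=L) for n in n_ha_values]


def select_n(scan_fits: Sequence[Sequence[NMCFit]], tol: float = 0.05) -> int:
    """Choose the effective site number from per-curve scans.

    Takes the median mse across curves at each n and returns the smallest n
    whose median mse is within ``tol`` (relative) of the overall minimum —
    preferring parsimony among near-equivalent fits.
    """
    by_n: dict[int, list[float]] = {}
    for fits in scan_fits:
        for f in fits:
            by_n.setdefault(f.n_ha, []).append(f.mse)
    ns = sorted(by_n)
    med = {n: float(np.median(by_n[n])) for n in ns}
    best = min(med.values())
    for n in ns:
        if med[n] <= best * (1 + tol) + 1e-15:
            return n
    return ns[-1]


def summarize_nmc(fits: Sequence[NMCFit]) -> list[NMCSummary]:
    """Group fits by model label; medians of c and r over accepted fits only."""
    if not fits:
        raise ValueError("no fits to summarize")
    labels: dict[str, list[NMCFit]] = {}
    for f in fits:
        labels.setdefault(f.model, []).append(f)
    out = []
    for label in sorted(labels):
        group = labels[label]
        acc = [f for f in group if f.accepted]
        if acc:
            out.append(
                NMCSummary(
                    model=label,
                    n_total=len(group),
                    n_accepted=len(acc),
                    median_c=float(np.median([f.c for f in acc])),
                    median_r=float(np.median([f.r for f in acc])),
                )
            )
        else:
            out.append(NMCSummary(model=label, n_total=len(group), n_accepted=0))
    return out
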