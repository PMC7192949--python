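"""Lipid flip-flop energetics: WHAM, barriers, and pore-nucleation density.

The free-energy barrier for moving a lipid head group from the outer leaflet
to the bilayer midplane (the flip-flop barrier, ``dG_flip``) controls how
readily a membrane nucleates a pore.  The chain implemented here is

    umbrella windows  --WHAM-->  PMF G(x)  --barrier-->  dG_flip
    dG_flip  -->  rho = exp(-dG_flip / kT) / A_lip  --fit-->  rho(C) = rho0 * exp(kappa * C)

where ``rho`` is the pore-nucleation density per membrane area, ``A_lip`` the
area per lipid, and ``C`` the membrane mean curvature.  WHAM is the standard
self-consistent weighted-histogram estimator over binned biased samples, with
bootstrap resampling for pointwise errors.

Units: nm for the reaction coordinate, kJ/mol for energies, K for temperature.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant in kJ mol^-1 K^-1 (molar gas constant).
KB = 0.008314


class OverlapError(RuntimeError):
    """Adjacent umbrella windows share no occupied histogram bins."""


class ConvergenceError(RuntimeError):
    """WHAM self-consistent iteration did not reach tolerance."""


@dataclass
class Window:
    """One umbrella window: harmonic bias 0.5*k*(x-center)^2 plus samples."""

    center: float
    spring_k: float  # kJ mol^-1 nm^-2
    samples: np.ndarray  # reaction-coordinate values, nm

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1)
        if self.spring_k <= 0:
            raise ValueError("spring_k must be positive")


@dataclass
class UmbrellaDataset:
    """Biased-sampling windows along one reaction coordinate."""

    windows: list[Window]
    temperature: float = 305.0

    def __post_init__(self) -> None:
        if len(self.windows) < 2:
            raise ValueError("need at least 2 umbrella windows")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kt(self) -> float:
        return KB * self.temperature


@dataclass
class PMFProfile:
    """Free-energy curve G(x) with pointwise errors, anchored to min(G) = 0."""

    x: np.ndarray
    G: np.ndarray
    G_error: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).reshape(-1)
        self.G = np.asarray(self.G, dtype=float).reshape(-1)
        if self.G_error is None:
            self.G_error = np.zeros_like(self.G)
        self.G_error = np.asarray(self.G_error, dtype=float).reshape(-1)
        if len(self.x) != len(self.G):
            raise ValueError("x and G length mismatch")

    def anchored(self) -> "PMFProfile":
        return PMFProfile(self.x, self.G - np.nanmin(self.G), self.G_error)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.x, self.G)


@dataclass
class Barrier:
    """Flip-flop barrier: max G along the path from the start-region minimum."""

    value: float
    error: float
    x_start: float
    x_top: float
    at_edge: bool = False  # True when the profile is monotone (no interior max)


@dataclass
class NucleationModel:
    """Pore-nucleation densities vs curvature with exponential fit."""

    curvature: np.ndarray  # nm^-1
    dG_flip: np.ndarray  # kJ/mol
    temperature: float
    A_lip: float  # nm^2
    rho: np.ndarray = field(init=False)  # nm^-2
    rho0: float = field(init=False, default=np.nan)
    kappa: float = field(init=False, default=np.nan)
    fit_residual: float = field(init=False, default=np.nan)

    def __post_init__(self) -> None:
        self.curvature = np.asarray(self.curvature, dtype=float).reshape(-1)
        self.dG_flip = np.asarray(self.dG_flip, dtype=float).reshape(-1)
        self.rho = np.array(
            [nucleation_density(g, self.temperature, self.A_lip) for g in self.dG_flip]
        )

    def fit(self) -> tuple[float, float, float]:
        self.rho0, self.kappa, self.fit_residual = fit_exponential(
            list(zip(self.curvature, self.rho))
        )
        return self.rho0, self.kappa, self.fit_residual


def _window_histograms(
    data: UmbrellaDataset, edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    counts = np.array(
        [np.histogram(w.samples, bins=edges)[0] for w in data.windows], dtype=float
    )
    sizes = np.array([len(w.samples) for w in data.windows], dtype=float)
    return counts, sizes


def _check_overlap(data: UmbrellaDataset, counts: np.ndarray) -> None:
    """Consecutive windows (sorted by center) must share occupied bin support."""
    order = np.argsort([w.center for w in data.windows])
    occ = counts > 0
    for a, b in zip(order[:-1], order[1:]):
        if not np.any(occ[a] & occ[b]):
            ca, cb = data.windows[a].center, data.windows[b].center
            raise OverlapError(
                f"umbrella windows at x0={ca:g} and x0={cb:g} nm share no occupied "
                "histogram bins; the sampling gap between them cannot be bridged"
            )


def _wham_iterate(
    counts: np.ndarray,
    sizes: np.ndarray,
    bias: np.ndarray,
    kt: float,
    tol: float,
    max_iter: int,
    f_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent WHAM on binned samples.

    counts : (n_windows, n_bins) per-window histograms
    bias : (n_windows, n_bins) bias energy w_i(x_j), kJ/mol
    Returns (unnormalized probabilities p_j, window offsets f_i).
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp

    n_j = counts.sum(axis=0)
    A = np.exp(-bias / kt)  # underflow to 0 far from each window is harmless
    f = np.zeros(len(sizes)) if f_init is None else f_init.copy()
    occupied = n_j > 0

    # The WHAM equations are the stationary point of a convex negative
    # log-likelihood in the window offsets; L-BFGS gets near the optimum in a
    # handful of evaluations and the self-consistent loop below polishes to
    # tolerance (plain fixed-point iteration alone converges geometrically
    # with rate near 1 when many windows overlap).
    lnN = np.log(sizes)
    b = bias / kt
    nj_occ = n_j[occupied]
    b_occ = b[:, occupied]

    def nll(g: np.ndarray) -> tuple[float, np.ndarray]:
        M = g[:, None] - b_occ + lnN[:, None]
        S = logsumexp(M, axis=0)
        val = -np.dot(sizes, g) + np.dot(nj_occ, S)
        P = np.exp(M - S[None, :])
        grad = -sizes + P @ nj_occ
        return val, grad

    res = minimize(nll, f / kt, jac=True, method="L-BFGS-B")
    f = kt * (res.x - res.x[0])

    for _ in range(max_iter):
        g = np.exp(f / kt)
        denom = (sizes * g) @ A  # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(occupied & (denom > 0), n_j / denom, 0.0)
        s = A @ p  # (n_windows,)
        f_new = -kt * np.log(s)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            return p, f
    raise ConvergenceError(
        f"WHAM did not converge: residual {delta:.3g} kJ/mol after {max_iter} "
        f"iterations (tol {tol:g})"
    )


def wham(
    data: UmbrellaDataset,
    n_bins: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    n_bootstrap: int = 50,
    seed: int = 0,
) -> PMFProfile:
    """Estimate the unbiased PMF from umbrella windows by WHAM.

    The default bin width is half the median window spacing.  Pointwise errors
    come from ``n_bootstrap`` resamples of the per-window sample lists, each
    bootstrap profile re-anchored to zero at the mean profile's minimum bin.
    """
    centers_w = np.sort([w.center for w in data.windows])
    all_x = np.concatenate([w.samples for w in data.windows])
    lo, hi = float(all_x.min()), float(all_x.max())
    if n_bins is None:
        # Bins must resolve the narrowest biased distribution: a bin much
        # wider than sqrt(kT/k) puts a whole window into one or two bins and
        # biases G by the within-bin variation of the biased density.
        spacing = float(np.median(np.diff(centers_w))) if len(centers_w) > 1 else 0.1
        sigma_min = math.sqrt(
            data.kt / max(w.spring_k for w in data.windows)
        )
        width = min(spacing / 2.0, sigma_min / 2.0)
        n_bins = max(10, int(np.ceil((hi - lo) / width)))
    edges = np.linspace(lo, hi + 1e-12, n_bins + 1)
    x = 0.5 * (edges[:-1] + edges[1:])

    counts, sizes = _window_histograms(data, edges)
    _check_overlap(data, counts)

    kt = data.kt
    bias = np.array(
        [0.5 * w.spring_k * (x - w.center) ** 2 for w in data.windows]
    )
    p, f = _wham_iterate(counts, sizes, bias, kt, tol, max_iter)

    occupied = p > 0
    G = np.full_like(x, np.nan)
    G[occupied] = -kt * np.log(p[occupied])
    anchor = int(np.nanargmin(G))
    G -= G[anchor]

    err = np.zeros_like(G)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_bootstrap):
            bw = []
            for w in data.windows:
                idx = rng.integers(0, len(w.samples), len(w.samples))
                bw.append(Window(w.center, w.spring_k, w.samples[idx]))
            bc, bs = _window_histograms(
                UmbrellaDataset(bw, data.temperature), edges
            )
            try:
                bp, _ = _wham_iterate(bc, bs, bias, kt, tol, max_iter, f_init=f)
            except ConvergenceError:
                continue
            with np.errstate(divide="ignore"):
                bG = np.where(bp > 0, -kt * np.log(np.where(bp > 0, bp, 1.0)), np.nan)
            if np.isfinite(bG[anchor]):
                boots.append(bG - bG[anchor])
        if boots:
            err = np.nanstd(np.asarray(boots), axis=0, ddof=1)

    keep = np.isfinite(G)
    return PMFProfile(x[keep], G[keep], err[keep]).anchored()


def barrier(
    profile: PMFProfile,
    start_region: tuple[float, float],
    end: float | None = None,
) -> Barrier:
    """Flip-flop barrier dG_flip from the start-region minimum to ``end``.

    ``end`` defaults to the far edge of the profile (the bilayer midplane in
    the flip-flop convention where the coordinate runs from the outer leaflet
    head-group region toward the midplane).  A profile that rises monotonically
    to ``end`` has no interior maximum; the edge value is returned with
    ``at_edge=True``.
    """
    a, b = sorted(start_region)
    x, G, E = profile.x, profile.G, profile.G_error
    if b < x[0] or a > x[-1]:
        raise ValueError(
            f"start_region [{a:g}, {b:g}] outside profile domain "
            f"[{x[0]:g}, {x[-1]:g}]"
        )
    a, b = max(a, float(x[0])), min(b, float(x[-1]))
    if end is None:
        end = float(x[-1])
    in_start = (x >= a) & (x <= b)
    if not np.any(in_start):
        raise ValueError("start_region contains no profile points")
    i_min = np.nonzero(in_start)[0][np.argmin(G[in_start])]
    path = slice(i_min, int(np.searchsorted(x, end, side="right")))
    i_top = i_min + int(np.argmax(G[path]))
    value = float(G[i_top] - G[i_min])
    err = float(np.hypot(E[i_top], E[i_min]))
    # Flagged when the profile rises all the way to its own final point: a
    # monotone profile with no maximum inside the sampled domain.
    at_edge = i_top == len(x) - 1
    return Barrier(value, err, float(x[i_min]), float(x[i_top]), at_edge=at_edge)


def nucleation_density(dG: float, T: float, A_lip: float) -> float:
    """Pore-nucleation density rho = exp(-dG / (kB*T)) / A_lip, in nm^-2.

    Underflow of the Boltzmann factor returns 0.0.
    """
    if A_lip <= 0:
        raise ValueError("A_lip must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    with np.errstate(under="ignore"):
        return float(np.exp(-dG / (KB * T)) / A_lip)


def fit_exponential(
    model_points: list[tuple[float, float]]
) -> tuple[float, float, float]:
    """Fit rho(C) = rho0 * exp(kappa * C) by least squares on ln(rho).

    Returns (rho0, kappa, residual) where residual is the RMS of the
    log-space fit residuals.  Exact (residual ~ machine epsilon) when the
    points were generated from the model.
    """
    pts = np.asarray(model_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (C, rho) points")
    C, rho = pts[:, 0], pts[:, 1]
    if np.any(rho <= 0):
        raise ValueError("all rho values must be positive")
    kappa, ln_rho0 = np.polyfit(C, np.log(rho), 1)
    resid = np.log(rho) - (ln_rho0 + kappa * C)
    return float(np.exp(ln_rho0)), float(kappa), float(np.sqrt(np.mean(resid**2)))


__all__ = [
    "KB",
    "Window",
    "UmbrellaDataset",
    "PMFProfile",
    "Barrier",
    "NucleationModel",
    "OverlapError",
    "ConvergenceError",
    "wham",
    "barrier",
    "nucleation_density",
    "fit_exponential",
]
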