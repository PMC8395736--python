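"""WHAM reconstruction of the potential of mean force from umbrella windows.

Given umbrella windows — samples of a 1D reaction coordinate drawn
under harmonic biases U_i(x) = k_i/2 (x - c_i)² — the weighted
histogram analysis method solves the self-consistent equations

    p(x_b) = Σ_i n_ib / Σ_i N_i exp(-β [U_i(x_b) - f_i])
    exp(-β f_i) = Σ_b p(x_b) exp(-β U_i(x_b))

for the unbiased bin probabilities p and per-window free-energy shifts
f_i, iterated until the largest shift change falls below a tolerance.
The PMF is -kT ln p, shifted so its minimum is zero. Bins that no
window populated are reported as NaN, never zero-filled.

The binding strength is the mean free energy over an unbound plateau
relative to the PMF minimum, reported negative and in kcal/mol; per-site
strengths are aggregated as mean ± sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB, KJ_PER_KCAL
from .synthetic import UmbrellaWindowSample


class ConvergenceError(RuntimeError):
    """WHAM could not proceed (e.g. disjoint window coverage)."""


@dataclass(frozen=True)
class WhamConfig:
    bin_edges: np.ndarray  # nm, strictly increasing
    temperature: float = 320.0  # K
    tolerance: float = 1e-6  # kJ/mol, max shift change
    max_iterations: int = 100_000

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class PMFProfile:
    bin_centers: np.ndarray  # nm
    free_energy: np.ndarray  # kJ/mol; NaN in unpopulated bins; min == 0
    window_shifts: np.ndarray  # kJ/mol, one per window
    converged: bool
    n_iterations: int
    temperature: float

    @property
    def populated(self) -> np.ndarray:
        return np.isfinite(self.free_energy)


def wham(
    windows: list[UmbrellaWindowSample],
    config: WhamConfig,
    initial_shifts: np.ndarray | None = None,
) -> PMFProfile:
    """Self-consistent WHAM over histogrammed umbrella windows."""
    if not windows:
        raise ValueError("need at least one window")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ValueError("windows sampled at different temperatures")
    beta = 1.0 / (KB * config.temperature)
    edges = config.bin_edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins, n_win = len(centers), len(windows)

    counts = np.zeros((n_win, n_bins))
    N = np.zeros(n_win)
    for i, w in enumerate(windows):
        h, _ = np.histogram(w.samples, bins=edges)
        counts[i] = h
        N[i] = h.sum()
    total_counts = counts.sum(axis=0)
    populated = total_counts > 0
    if not populated.any():
        raise ConvergenceError("no samples fall inside the requested bins")
    if n_win > 1:
        # overlap diagnostic: each populated bin should be reachable, and
        # adjacent windows should share support
        per_win_pop = counts > 0
        isolated = [
            i
            for i in range(n_win)
            if not any(
                (per_win_pop[i] & per_win_pop[j]).any()
                for j in range(n_win)
                if j != i
            )
        ]
        if isolated:
            raise ConvergenceError(
                f"windows {isolated} share no populated bins with any other "
                "window; coverage is disjoint and the shifts are not determined"
            )

    bias = 0.5 * np.array([w.bias_k for w in windows])[:, None] * (
        centers[None, :] - np.array([w.bias_center for w in windows])[:, None]
    ) ** 2  # (n_win, n_bins), kJ/mol

    f = np.zeros(n_win) if initial_shifts is None else np.array(initial_shifts, float)
    log_boltz = -beta * bias  # constant part
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        # denominator per bin: sum_i N_i exp(-beta (bias_ib - f_i))
        logw = log_boltz + beta * f[:, None] + np.log(np.maximum(N, 1e-300))[:, None]
        m = logw.max(axis=0)
        denom = np.exp(logw - m).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_p = np.where(
                populated, np.log(np.maximum(total_counts, 1e-300)) - m - np.log(denom), -np.inf
            )
        # new shifts: exp(-beta f_i) = sum_b p_b exp(-beta bias_ib)
        log_sum = _logsumexp(log_p[None, :] + log_boltz, axis=1)
        f_new = -log_sum / beta
        f_new -= f_new[0]  # gauge: first window defines zero
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < config.tolerance:
            converged = True
            break

    logw = log_boltz + beta * f[:, None] + np.log(np.maximum(N, 1e-300))[:, None]
    m = logw.max(axis=0)
    denom = np.exp(logw - m).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p = np.where(
            populated, np.log(np.maximum(total_counts, 1e-300)) - m - np.log(denom), np.nan
        )
    fe = -log_p / beta
    fe = fe - np.nanmin(fe)
    return PMFProfile(
        bin_centers=centers,
        free_energy=fe,
        window_shifts=f,
        converged=converged,
        n_iterations=it,
        temperature=config.temperature,
    )


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(np.where(np.isfinite(a), a, -np.inf), axis=axis, keepdims=True)
    out = m.squeeze(axis) + np.log(
        np.exp(np.where(np.isfinite(a), a, -np.inf) - m).sum(axis=axis)
    )
    return out


def binding_strength(
    profile: PMFProfile, unbound_region: tuple[float, float]
) -> float:
    """Well depth relative to the unbound plateau, negative, kcal/mol."""
    lo, hi = unbound_region
    mask = (profile.bin_centers >= lo) & (profile.bin_centers <= hi) & profile.populated
    if not mask.any():
        raise ValueError(f"no populated bins inside the unbound region ({lo}, {hi}) nm")
    plateau = float(profile.free_energy[mask].mean())
    depth_kj = plateau - float(np.nanmin(profile.free_energy))
    return -depth_kj / KJ_PER_KCAL


def aggregate_binding_sites(strengths: list[float]) -> tuple[float, float]:
    """Mean and sample standard deviation over per-site binding strengths.

    A single site has no dispersion estimate: the sd is reported as 0.0
    by convention.
    """
    if not strengths:
        raise ValueError("no binding sites")
    arr = np.asarray(strengths, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def bootstrap_binding_strength(
    windows: list[UmbrellaWindowSample],
    config: WhamConfig,
    unbound_region: tuple[float, float],
    n_boot: int = 20,
    seed: int = 0,
) -> tuple[float, float]:
    """Window-resampling bootstrap of the binding strength: (mean, sd)."""
    rng = np.random.default_rng(seed)
    vals = []
    n = len(windows)
    for _ in range(n_boot):
        pick = sorted(set(rng.integers(0, n, size=n).tolist()))
        try:
            prof = wham([windows[i] for i in pick], config)
            vals.append(binding_strength(prof, unbound_region))
        except (ConvergenceError, ValueError):
            continue
    if not vals:
        raise ConvergenceError("no bootstrap replicate produced a usable profile")
    arr = np.asarray(vals)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
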