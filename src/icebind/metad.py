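"""Collective variables and well-tempered metadynamics on toy systems.

The collective variables (rational switching function, smooth coordination
number, radius of gyration via :mod:`icebind.conformation`) match the
definitions used in enhanced-sampling engines.  The metadynamics engine runs
overdamped Langevin dynamics directly on a one-dimensional CV moving on an
analytic potential — every estimator property (well-tempered damping of the
Gaussian heights, bias-to-free-energy inversion, Tiwary–Parrinello
reweighting, replicate averaging) is then testable against closed forms.

Units: energies kJ/mol, lengths nm, time ps, temperatures K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Configuration, minimum_image
from .conformation import KB

__all__ = [
    "SwitchingParams",
    "switching_value",
    "coordination_number",
    "WTMetaDParams",
    "BiasPotential",
    "DoubleWell",
    "MetadTrace",
    "wtmetad_run",
    "tiwary_reweight",
    "FEProfile",
    "replicate_average",
]


# ---------------------------------------------------------------------------
# collective variables
# ---------------------------------------------------------------------------


@dataclass
class SwitchingParams:
    """Rational switching function s(r) = (1-(r/r0)^n) / (1-(r/r0)^m).

    Defaults r0 = 0.55 nm, n = 6, m = 12.  Even exponents keep s positive
    beyond r0; s is continuous at r = r0 with value n/m.
    """

    r0: float = 0.55
    n: int = 6
    m: int = 12

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (0 < self.n < self.m):
            raise ValueError("need 0 < n < m")
        if self.n % 2 or self.m % 2:
            raise ValueError("n and m must be even")


def switching_value(r, params: SwitchingParams | None = None):
    """Evaluate the switching function; scalar or array ``r`` >= 0."""
    params = params or SwitchingParams()
    x = np.asarray(r, dtype=float) / params.r0
    if np.any(x < 0):
        raise ValueError("r must be non-negative")
    xn = x**params.n
    xm = x**params.m
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (1.0 - xn) / (1.0 - xm)
    # remove the 0/0 at r = r0: the limit is n/m
    near = np.isclose(x, 1.0, rtol=0.0, atol=1e-9)
    if np.any(near):
        s = np.where(near, params.n / params.m, s)
    return float(s) if np.isscalar(r) else s


def coordination_number(
    config: Configuration,
    set_a,
    set_b=None,
    params: SwitchingParams | None = None,
) -> float:
    """Smooth contact count CN = sum_ij s(r_ij) with PBC minimum image.

    Inter-mode (``set_b`` given): sum over all pairs (i in A, j in B);
    A and B must be disjoint.  Self-mode (``set_b`` None): sum over the
    N(N-1)/2 unordered pairs within ``set_a``.
    """
    params = params or SwitchingParams()
    a = np.asarray(set_a, dtype=int)
    if len(a) == 0:
        raise ValueError("set_a is empty")
    pos = config.positions
    if set_b is not None:
        b = np.asarray(set_b, dtype=int)
        if len(b) == 0:
            raise ValueError("set_b is empty")
        if np.intersect1d(a, b).size:
            raise ValueError("set_a and set_b overlap in inter-mode")
        d = minimum_image(pos[a][:, None, :] - pos[b][None, :, :], config.box)
        r = np.linalg.norm(d, axis=2)
        return float(np.sum(switching_value(r, params)))
    iu, ju = np.triu_indices(len(a), k=1)
    d = minimum_image(pos[a[iu]] - pos[a[ju]], config.box)
    r = np.linalg.norm(d, axis=1)
    return float(np.sum(switching_value(r, params)))


# ---------------------------------------------------------------------------
# toy system + WTMetaD engine
# ---------------------------------------------------------------------------


@dataclass
class WTMetaDParams:
    """Well-tempered metadynamics parameters.

    ``W`` initial Gaussian height (kJ/mol), ``sigma`` Gaussian width (CV
    units), ``gamma`` bias factor (> 1), ``stride`` steps between deposits,
    ``T`` temperature (K).  The well-tempered delta-T is (gamma - 1) T.
    """

    W: float = 1.0
    sigma: float = 0.1
    gamma: float = 20.0
    stride: int = 500
    T: float = 300.0

    def __post_init__(self) -> None:
        if self.W <= 0 or self.sigma <= 0 or self.stride < 1:
            raise ValueError("need W > 0, sigma > 0, stride >= 1")
        if self.gamma <= 1:
            raise ValueError("bias factor gamma must exceed 1")

    @property
    def delta_T(self) -> float:
        return (self.gamma - 1.0) * self.T


@dataclass
class DoubleWell:
    """Symmetric quartic double well U(s) = h ((s/a)^2 - 1)^2.

    Minima at s = +-a, barrier height ``h`` (kJ/mol) at s = 0.
    """

    barrier: float = 10.0
    a: float = 1.0

    def energy(self, s):
        x = np.asarray(s, dtype=float) / self.a
        return self.barrier * (x * x - 1.0) ** 2

    def force(self, s):
        """-dU/ds."""
        x = np.asarray(s, dtype=float) / self.a
        return -4.0 * self.barrier * x * (x * x - 1.0) / self.a


@dataclass
class BiasPotential:
    """Deposited Gaussian kernels with well-tempered bookkeeping."""

    centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    heights: np.ndarray = field(default_factory=lambda: np.empty(0))
    deposit_steps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    sigma: float = 0.1
    gamma: float = 20.0
    T: float = 300.0

    @property
    def n_kernels(self) -> int:
        return len(self.centers)

    def evaluate(self, s, n_kernels: int | None = None):
        """Bias V(s) from the first ``n_kernels`` kernels (all by default)."""
        k = self.n_kernels if n_kernels is None else n_kernels
        x = np.atleast_1d(np.asarray(s, dtype=float))
        if k == 0:
            out = np.zeros_like(x)
        else:
            diff = (x[:, None] - self.centers[None, :k]) / self.sigma
            out = np.sum(self.heights[None, :k] * np.exp(-0.5 * diff * diff), axis=1)
        return float(out[0]) if np.isscalar(s) else out

    def free_energy_estimate(self, grid: np.ndarray) -> np.ndarray:
        """F(s) ~ -gamma/(gamma-1) V(s), min-shifted, on ``grid``."""
        v = self.evaluate(grid)
        f = -self.gamma / (self.gamma - 1.0) * v
        return f - f.min()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": self.deposit_steps, "center": self.centers, "height": self.heights}
        )


@dataclass
class MetadTrace:
    """Sampled CV values and the number of kernels active at each sample."""

    steps: np.ndarray
    cv: np.ndarray
    kernels_before: np.ndarray  # kernels deposited strictly before each sample
    dt: float
    sample_stride: int


def wtmetad_run(
    potential,
    metad: WTMetaDParams,
    n_steps: int,
    seed: int,
    dt: float = 0.005,
    diffusion: float = 0.05,
    s0: float = -1.0,
    grid: np.ndarray | None = None,
    sample_stride: int = 10,
) -> tuple[MetadTrace, BiasPotential]:
    """Overdamped Langevin dynamics on a 1-D CV with WTMetaD biasing.

    The CV itself is the dynamical coordinate:
    ds = beta D (F_pot + F_bias) dt + sqrt(2 D dt) xi.  Every ``stride``
    steps a Gaussian of height W exp(-V(s)/(kB dT)) is deposited at the
    current CV value.  The bias (and its gradient) is accumulated on
    ``grid`` and linearly interpolated, PLUMED-style.

    Returns the sampled trace and the deposited kernels; both are
    reproducible bit-for-bit for a fixed seed.
    """
    if grid is None:
        grid = np.linspace(-2.5, 2.5, 1001)
    grid = np.asarray(grid, dtype=float)
    lo, hi = float(grid[0]), float(grid[-1])
    ng = len(grid)
    h = (hi - lo) / (ng - 1)
    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * metad.T)
    kbdT = KB * metad.delta_T
    mobility = diffusion * beta * dt
    noise_scale = math.sqrt(2.0 * diffusion * dt)

    v_grid = np.zeros(ng)  # bias values on the grid
    g_grid = np.zeros(ng)  # bias gradient on the grid

    centers: list[float] = []
    heights: list[float] = []
    dep_steps: list[int] = []

    noises = rng.standard_normal(n_steps)

    def interp(arr, s):
        if s <= lo:
            return arr[0]
        if s >= hi:
            return arr[-1]
        j = int((s - lo) / h)
        f = (s - lo) / h - j
        return arr[j] * (1.0 - f) + arr[j + 1] * f

    s = float(s0)
    n_samples = n_steps // sample_stride + 1
    cv_out = np.empty(n_samples)
    step_out = np.empty(n_samples, dtype=int)
    kern_out = np.empty(n_samples, dtype=int)
    n_out = 0

    sig2 = metad.sigma * metad.sigma
    for step in range(n_steps):
        if step % sample_stride == 0:
            cv_out[n_out] = s
            step_out[n_out] = step
            kern_out[n_out] = len(centers)
            n_out += 1
        if step > 0 and step % metad.stride == 0:
            height = metad.W * math.exp(-interp(v_grid, s) / kbdT)
            centers.append(s)
            heights.append(height)
            dep_steps.append(step)
            d = grid - s
            gauss = height * np.exp(-0.5 * d * d / sig2)
            v_grid += gauss
            g_grid += gauss * (-d / sig2)
        f_tot = float(potential.force(s)) + interp(g_grid, s) * -1.0
        s = s + mobility * f_tot + noise_scale * noises[step]

    trace = MetadTrace(
        steps=step_out[:n_out],
        cv=cv_out[:n_out],
        kernels_before=kern_out[:n_out],
        dt=dt,
        sample_stride=sample_stride,
    )
    bias = BiasPotential(
        centers=np.array(centers),
        heights=np.array(heights),
        deposit_steps=np.array(dep_steps, dtype=int),
        sigma=metad.sigma,
        gamma=metad.gamma,
        T=metad.T,
    )
    return trace, bias


# ---------------------------------------------------------------------------
# reweighting
# ---------------------------------------------------------------------------


@dataclass
class FEProfile:
    """Free-energy profile on a CV grid, minimum-shifted to zero.

    Bins never visited carry NaN.  ``stderr`` is the per-bin standard error
    across replicas (zeros for a single run).
    """

    grid: np.ndarray  # bin centres
    dG: np.ndarray
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cv": self.grid,
                "dG": self.dG,
                "stderr": np.zeros_like(self.dG) if self.stderr is None else self.stderr,
            }
        )


def _c_of_t(v_grid: np.ndarray, gamma: float, beta: float) -> float:
    """Time-dependent reweighting constant c(t) from the current bias.

    c(t) = (1/beta) ln [ int e^{beta gamma V/(gamma-1)} / int e^{beta V/(gamma-1)} ];
    the grid spacing cancels in the ratio.
    """
    g = gamma / (gamma - 1.0)
    a = beta * g * v_grid
    b = beta * v_grid / (gamma - 1.0)
    amax, bmax = a.max(), b.max()
    num = math.log(np.sum(np.exp(a - amax))) + amax
    den = math.log(np.sum(np.exp(b - bmax))) + bmax
    return (num - den) / beta


def tiwary_reweight(
    trace: MetadTrace,
    bias: BiasPotential,
    metad: WTMetaDParams,
    grid: np.ndarray | None = None,
    burn_in: float = 0.2,
) -> FEProfile:
    """Reweight a metadynamics trace to the unbiased free energy.

    Each sample carries weight exp(beta (V(s_t, t) - c(t))) with V the bias
    accumulated at the sample's time and c(t) the well-tempered
    normalisation integrated over the full sampled range at the most recent
    deposit.  The weighted histogram gives dG = -kB T ln p,
    minimum-shifted.  ``grid`` is the reporting window: samples outside it
    are excluded from the histogram (but still enter c(t)).  The first
    ``burn_in`` fraction of samples is discarded.
    """
    if grid is None:
        grid = np.linspace(-2.0, 2.0, 81)
    grid = np.asarray(grid, dtype=float)
    if len(trace.cv) == 0:
        raise ValueError("empty trace")
    beta = 1.0 / (KB * metad.T)
    start = int(len(trace.cv) * burn_in)
    cv = trace.cv[start:]
    kb4 = trace.kernels_before[start:]
    inside = (cv >= grid[0]) & (cv <= grid[-1])
    if np.mean(inside) < 0.5:
        raise ValueError(
            f"grid does not cover the sampled CV range "
            f"({1 - np.mean(inside):.1%} of samples outside)"
        )

    # bias and c(t) per deposit epoch, on an internal grid spanning
    # everything that was sampled (the quadrature for c(t) must see the
    # whole biased region, not just the reporting window)
    n_kernels = bias.n_kernels
    lo = min(float(grid[0]), float(cv.min())) - 0.2
    hi = max(float(grid[-1]), float(cv.max())) + 0.2
    if n_kernels:
        lo = min(lo, float(bias.centers.min()) - 0.2)
        hi = max(hi, float(bias.centers.max()) + 0.2)
    spacing = min(bias.sigma / 4.0, float(np.min(np.diff(grid))))
    fine = np.linspace(lo, hi, int(np.ceil((hi - lo) / spacing)) + 1)
    v_fine = np.zeros(len(fine))
    c_by_epoch = np.empty(n_kernels + 1)
    c_by_epoch[0] = 0.0
    sig2 = bias.sigma**2
    for k in range(n_kernels):
        d = fine - bias.centers[k]
        v_fine += bias.heights[k] * np.exp(-0.5 * d * d / sig2)
        c_by_epoch[k + 1] = _c_of_t(v_fine, bias.gamma, beta)

    # per-sample log-weights: V at the sample's epoch, interpolated on the
    # fine grid; samples are in time order, so epochs come in runs
    logw = np.empty(len(cv))
    v_grid = np.zeros(len(fine))
    epoch = 0
    boundaries = np.searchsorted(kb4, np.arange(n_kernels + 2))
    for k in range(n_kernels + 1):
        sel = slice(boundaries[k], boundaries[k + 1])
        if sel.start == sel.stop:
            continue
        while epoch < k:
            d = fine - bias.centers[epoch]
            v_grid += bias.heights[epoch] * np.exp(-0.5 * d * d / sig2)
            epoch += 1
        logw[sel] = beta * (np.interp(cv[sel], fine, v_grid) - c_by_epoch[k])

    logw -= logw.max()
    w = np.exp(logw)
    edges = np.concatenate(
        [[grid[0] - (grid[1] - grid[0]) / 2], (grid[:-1] + grid[1:]) / 2, [grid[-1] + (grid[-1] - grid[-2]) / 2]]
    )
    hist, _ = np.histogram(cv, bins=edges, weights=w)
    counts, _ = np.histogram(cv, bins=edges)
    dG = np.full(len(grid), np.nan)
    # a bin needs both visits and non-underflowed weight to carry an estimate
    visited = (counts > 0) & (hist > 0)
    dG[visited] = -KB * metad.T * np.log(hist[visited])
    dG -= np.nanmin(dG)
    return FEProfile(grid=grid, dG=dG, stderr=np.zeros(len(grid)))


def replicate_average(profiles: list[FEProfile]) -> FEProfile:
    """Mean and standard error of the mean across replicate profiles.

    Bins not visited by every replica are NaN in the output.  The mean is
    re-shifted so its minimum over commonly sampled bins is zero.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two replicate profiles")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if len(p.grid) != len(grid) or not np.allclose(p.grid, grid):
            raise ValueError("replicate profiles must share a common grid")
    stack = np.vstack([p.dG for p in profiles])
    common = np.all(np.isfinite(stack), axis=0)
    mean = np.full(len(grid), np.nan)
    sem = np.full(len(grid), np.nan)
    mean[common] = stack[:, common].mean(axis=0)
    n = len(profiles)
    sem[common] = stack[:, common].std(axis=0, ddof=1) / math.sqrt(n)
    mean -= np.nanmin(mean)
    return FEProfile(grid=grid, dG=mean, stderr=sem)
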