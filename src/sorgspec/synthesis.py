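"""Synthetic FT-NIR study generator.

Emulates a 98-sample sorghum grain study: per-analyte concentrations drawn
from truncated normals matched to published descriptive statistics, and
absorbance spectra rendered as Beer-Lambert linear mixtures of Gaussian-band
pure-component spectra, degraded by multiplicative scatter, additive offset,
linear baseline tilt and i.i.d. noise.  Whole-grain scans get a wider scatter
spread than flours (hull / particle-size scattering).

The forward model for sample i on grid nu is

    x_i = b_i * (sum_a c_{ia} s_a(nu)) + a_i + t_i * (nu - nu_bar)/(nu_max - nu_min) + eps_i

with b_i ~ scatter, a_i ~ offset, t_i ~ tilt, eps_i ~ N(0, noise_sd^2) i.i.d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .grading import GradingRules, grade_sample
from .io import ANALYTES, AlignedDataset, ReferenceChemistry, SpectraSet

#: instrument grid: 1,557 evenly spaced points spanning 4,000-10,000 cm^-1
N_VARIABLES = 1557
GRID_MIN, GRID_MAX = 4000.0, 10000.0


def default_grid() -> np.ndarray:
    return np.linspace(GRID_MIN, GRID_MAX, N_VARIABLES)


@dataclass(frozen=True)
class AnalyteStats:
    """Moments and range of one analyte's concentration (g kg^-1)."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"require min <= mean <= max, got {self}")
        if self.sd <= 0:
            raise ValueError("sd must be > 0")


# Calibration-subset descriptive statistics per grain morphology:
# (mean, sd, min, max) in g kg^-1 for each analyte.
HULLED_STATS: dict[str, AnalyteStats] = {
    "starch": AnalyteStats(546.95, 71.57, 376.98, 744.38),
    "protein": AnalyteStats(137.99, 17.13, 104.97, 185.01),
    "fat": AnalyteStats(36.41, 9.64, 13.99, 58.99),
    "tannin": AnalyteStats(15.18, 2.33, 11.01, 21.06),
    "cellulose": AnalyteStats(113.30, 19.96, 75.84, 181.85),
    "hemicellulose": AnalyteStats(66.28, 13.10, 26.03, 90.43),
    "lignin": AnalyteStats(67.90, 10.95, 31.39, 87.68),
    "ash": AnalyteStats(26.89, 3.51, 22.11, 36.37),
}

HULL_LESS_STATS: dict[str, AnalyteStats] = {
    "starch": AnalyteStats(645.06, 77.75, 519.91, 784.79),
    "protein": AnalyteStats(134.08, 12.35, 113.99, 156.99),
    "fat": AnalyteStats(37.81, 7.55, 21.97, 53.18),
    "tannin": AnalyteStats(11.10, 4.33, 1.32, 19.75),
    "cellulose": AnalyteStats(120.07, 38.30, 62.64, 216.86),
    "hemicellulose": AnalyteStats(35.30, 7.85, 19.70, 49.37),
    "lignin": AnalyteStats(39.40, 7.44, 22.03, 57.03),
    "ash": AnalyteStats(20.12, 2.70, 16.17, 25.83),
}

# Pooled whole-set statistics (all 98 samples scanned whole or milled).
POOLED_STATS: dict[str, AnalyteStats] = {
    "starch": AnalyteStats(589.24, 98.25, 298.67, 784.79),
    "protein": AnalyteStats(136.21, 14.84, 104.97, 185.01),
    "fat": AnalyteStats(36.83, 8.95, 13.99, 58.99),
    "tannin": AnalyteStats(12.99, 3.93, 1.32, 19.92),
    "cellulose": AnalyteStats(116.17, 30.27, 62.64, 216.86),
    "hemicellulose": AnalyteStats(56.04, 17.10, 26.03, 90.43),
    "lignin": AnalyteStats(56.78, 16.17, 27.10, 87.68),
    "ash": AnalyteStats(23.44, 4.44, 16.17, 36.37),
}


@dataclass(frozen=True)
class GaussianBand:
    center: float  # cm^-1
    width: float   # cm^-1 (Gaussian sigma)
    height: float  # absorbance per g kg^-1 at band center


# Band centers chosen at plausible NIR overtone/combination positions so the
# eight pure spectra are linearly independent; heights are relative weights,
# rescaled at library construction so realistic mixtures peak near 0.38 AU.
_BAND_TABLE: dict[str, tuple[tuple[float, float, float], ...]] = {
    "starch": ((4400, 90, 1.0), (4760, 110, 0.8), (5200, 140, 0.9), (6300, 200, 0.5), (8300, 260, 0.25)),
    "protein": ((4600, 80, 1.0), (4860, 100, 0.9), (5800, 160, 0.6), (6700, 210, 0.4)),
    "fat": ((4260, 70, 1.0), (5680, 130, 0.8), (8250, 240, 0.35)),
    "tannin": ((4670, 85, 1.0), (6000, 150, 0.7), (8700, 230, 0.3)),
    "cellulose": ((4280, 95, 0.9), (5480, 150, 1.0), (6800, 220, 0.45)),
    "hemicellulose": ((4390, 100, 1.0), (5980, 170, 0.8), (7000, 230, 0.4)),
    "lignin": ((4690, 110, 0.8), (5970, 140, 1.0), (8570, 250, 0.35)),
    "ash": ((5100, 180, 1.0), (7500, 300, 0.5)),
}

# residual matrix (moisture O-H, soluble sugars, other dry matter): broad bands
_MATRIX_BANDS: tuple[tuple[float, float, float], ...] = (
    (4800, 300, 0.6), (5150, 200, 1.0), (6900, 260, 0.8), (8400, 400, 0.3),
)


@dataclass
class BandLibrary:
    """Pure-component absorptivity spectra on the instrument grid.

    ``matrix`` is an optional absorptivity spectrum of the residual sample
    matrix (moisture, soluble sugars, other dry matter).  When present, each
    sample is completed to ``total_mass`` g kg^-1 by that component (mass
    closure), the constraint that makes absolute concentrations recoverable
    from scatter-normalised spectra; the clean mixture stays affine in the
    eight analyte concentrations, so the forward model is still exactly
    low-rank.  ``matrix=None`` gives the pure linear mixture.
    """

    grid: np.ndarray
    spectra: dict[str, np.ndarray]  # analyte -> absorptivity per g kg^-1
    matrix: np.ndarray | None = None
    total_mass: float = 1600.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        for name, s in self.spectra.items():
            s = np.asarray(s, dtype=float)
            if s.shape != self.grid.shape:
                raise ValueError(f"band spectrum for {name!r} off the grid")
            if np.any(s < 0):
                raise ValueError(f"negative absorptivity for {name!r}")
            self.spectra[name] = s
        if self.matrix is not None:
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.shape != self.grid.shape:
                raise ValueError("matrix spectrum off the grid")

    def mixture(self, concentrations: np.ndarray, analytes=ANALYTES) -> np.ndarray:
        """Clean Beer-Lambert mixture for rows of concentrations (g kg^-1)."""
        C = np.atleast_2d(np.asarray(concentrations, dtype=float))
        S = np.vstack([self.spectra[a] for a in analytes])
        clean = C @ S
        if self.matrix is not None:
            residual = np.clip(self.total_mass - C.sum(axis=1), 0.0, None)
            clean = clean + residual[:, None] * self.matrix
        return clean


def default_band_library(grid: np.ndarray | None = None, target_peak: float = 0.38) -> BandLibrary:
    """Build the default Gaussian band library.

    Heights are globally rescaled so that a mixture at the pooled mean
    concentrations peaks at ``target_peak`` absorbance units, matching the
    ~0.25-0.43 AU range typical of grain/flour FT-NIR scans.
    """
    if grid is None:
        grid = default_grid()

    def _bands(bands):
        s = np.zeros_like(grid)
        for center, width, height in bands:
            s += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
        return s

    spectra = {analyte: _bands(bands) for analyte, bands in _BAND_TABLE.items()}
    # the matrix component absorbs more weakly per unit mass than the analytes
    matrix = 0.25 * _bands(_MATRIX_BANDS)
    lib = BandLibrary(grid=grid, spectra=spectra, matrix=matrix)
    mean_conc = np.array([POOLED_STATS[a].mean for a in ANALYTES])
    peak = lib.mixture(mean_conc).max()
    scale = target_peak / peak
    return BandLibrary(
        grid=grid,
        spectra={a: s * scale for a, s in spectra.items()},
        matrix=matrix * scale,
    )


@dataclass(frozen=True)
class EffectModel:
    """Distributions of the per-sample measurement effects.

    scatter_spread: sd of the multiplicative factor b_i around 1 (truncated > 0.1)
    offset_sd: sd of the additive offset a_i (AU)
    tilt_sd: sd of the linear baseline-tilt coefficient t_i (AU over full grid)
    noise_sd: sd of i.i.d. noise (AU)
    format_spread: per-format multiplier applied to scatter/offset/tilt spreads
    """

    scatter_spread: float = 0.15
    offset_sd: float = 0.02
    tilt_sd: float = 0.02
    noise_sd: float = 5e-4
    format_spread: dict = field(
        default_factory=lambda: {
            "whole_grain": 2.0,
            "whole_grain_flour": 1.0,
            "hulled_flour": 1.0,
            "hull_less_flour": 1.0,
        }
    )

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.scatter_spread < 0:
            raise ValueError("scatter spread must be >= 0")


from functools import lru_cache


@lru_cache(maxsize=256)
def _matched_parent(s: AnalyteStats) -> tuple[float, float]:
    """Parent-normal (mu, sigma) whose [min, max]-truncation has the target moments.

    Table-style mean/sd are empirical moments of bounded data, so the
    truncated distribution itself (not its parent) must match them.  Solved
    numerically; falls back to the naive parent when the bounds make the
    target unreachable (e.g. sd close to the uniform limit of the interval).
    """
    from scipy import optimize, stats as sps

    # truncation beyond ~6 sigma on both sides is negligible
    if s.min <= s.mean - 6 * s.sd and s.max >= s.mean + 6 * s.sd:
        return s.mean, s.sd
    target = np.array([s.mean, s.sd])

    def gap(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (s.min - mu) / sigma, (s.max - mu) / sigma
        dist = sps.truncnorm(a, b, loc=mu, scale=sigma)
        return [dist.mean() - target[0], dist.std() - target[1]]

    sol = optimize.root(gap, x0=[s.mean, math.log(s.sd)], method="hybr")
    if sol.success and max(abs(np.asarray(gap(sol.x)))) < 1e-6 * s.sd:
        return float(sol.x[0]), float(math.exp(sol.x[1]))
    return s.mean, s.sd


def draw_concentrations(
    n: int,
    stats: dict[str, AnalyteStats],
    correlation: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "S",
) -> ReferenceChemistry:
    """Draw ``n`` samples of the eight analytes from truncated normals.

    Each analyte is a normal truncated to [min, max] by rejection, with the
    parent moment-matched so the *truncated* mean/sd equal the configured
    values; with a ``correlation`` matrix a truncated multivariate normal is
    used (rejection on the joint box; moments then hold approximately for
    strong correlations).  The seed fixes the output exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    missing = set(ANALYTES) - set(stats)
    if missing:
        raise ValueError(f"stats missing analytes: {sorted(missing)}")
    for a in ANALYTES:
        if stats[a].min > stats[a].max:
            raise ValueError(f"infeasible truncation for {a}")
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    parents = [_matched_parent(stats[a]) for a in ANALYTES]
    mean = np.array([m for m, _ in parents])
    sd = np.array([s for _, s in parents])
    lo = np.array([stats[a].min for a in ANALYTES])
    hi = np.array([stats[a].max for a in ANALYTES])
    k = len(ANALYTES)
    if correlation is not None:
        correlation = np.asarray(correlation, dtype=float)
        if np.min(np.linalg.eigvalsh(correlation)) < -1e-10:
            raise ValueError("correlation matrix is not positive semidefinite")
        if np.allclose(correlation, np.eye(k)):
            correlation = None

    out = np.empty((n, k))
    if correlation is None:
        # independent analytes: exact inverse-CDF truncated-normal sampling
        for j in range(k):
            a_j = (lo[j] - mean[j]) / sd[j]
            b_j = (hi[j] - mean[j]) / sd[j]
            if a_j < -8 and b_j > 8:  # truncation numerically irrelevant
                out[:, j] = mean[j] + sd[j] * rng.standard_normal(n)
            else:
                out[:, j] = sps.truncnorm.rvs(
                    a_j, b_j, loc=mean[j], scale=sd[j], size=n, random_state=rng
                )
    else:
        # Gaussian copula with rejection on the joint box; marginal moments
        # then hold only approximately (documented)
        cov = correlation * np.outer(sd, sd)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
        filled = 0
        while filled < n:
            m = max(2 * (n - filled), 16)
            draws = mean + rng.standard_normal((m, k)) @ chol.T
            good = draws[np.all((draws >= lo) & (draws <= hi), axis=1)]
            take = min(len(good), n - filled)
            out[filled : filled + take] = good[:take]
            filled += take
    ids = [f"{id_prefix}{i + 1:03d}" for i in range(n)]
    import pandas as pd

    return ReferenceChemistry(sample_ids=ids, analytes=pd.DataFrame(out, columns=list(ANALYTES)))


def render_spectra(
    conc: ReferenceChemistry,
    library: BandLibrary,
    effects: EffectModel | None = None,
    seed: int | np.random.Generator = 0,
    sample_format: str | list[str] = "whole_grain_flour",
) -> SpectraSet:
    """Render absorbance spectra from concentrations via the forward model."""
    if conc.n_samples == 0:
        raise ValueError("empty concentration table")
    effects = effects or EffectModel()
    rng = np.random.default_rng(seed)
    grid = library.grid
    n, p = conc.n_samples, grid.size
    if isinstance(sample_format, str):
        formats = [sample_format] * n
    else:
        formats = list(sample_format)
        if len(formats) != n:
            raise ValueError("sample_format length mismatch")
    clean = library.mixture(conc.analytes.to_numpy())
    mult = np.array([effects.format_spread.get(f, 1.0) for f in formats])
    b = 1.0 + effects.scatter_spread * mult * rng.standard_normal(n)
    b = np.clip(b, 0.1, None)  # scatter factors stay positive
    a = effects.offset_sd * mult * rng.standard_normal(n)
    t = effects.tilt_sd * mult * rng.standard_normal(n)
    ramp = (grid - grid.mean()) / (grid.max() - grid.min())
    X = b[:, None] * clean + a[:, None] + t[:, None] * ramp[None, :]
    if effects.noise_sd > 0:
        X = X + effects.noise_sd * rng.standard_normal((n, p))
    return SpectraSet(
        sample_ids=list(conc.sample_ids),
        wavenumbers=grid.copy(),
        absorbance=X,
        sample_format=formats,
    )


@dataclass
class StudyConfig:
    """Settings for a full simulated study.

    Defaults reproduce the study scale: 98 grain samples, 61 hulled and
    37 hull-less, scanned over 4,000-10,000 cm^-1 at 1,557 variables.
    """

    n_hulled: int = 61
    n_hull_less: int = 37
    scan_format: str = "whole_grain"
    effects: EffectModel = field(default_factory=EffectModel)
    correlation: np.ndarray | None = None
    rules: GradingRules = field(default_factory=GradingRules)
    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_hulled + self.n_hull_less


def _draw_study_chemistry(config: StudyConfig) -> ReferenceChemistry:
    rng = np.random.default_rng(config.seed)
    hulled = draw_concentrations(
        config.n_hulled, HULLED_STATS, config.correlation,
        seed=rng.integers(2**31), id_prefix="H",
    )
    hull_less = draw_concentrations(
        config.n_hull_less, HULL_LESS_STATS, config.correlation,
        seed=rng.integers(2**31), id_prefix="L",
    )
    import pandas as pd

    analytes = pd.concat([hulled.analytes, hull_less.analytes], axis=0)
    ids = hulled.sample_ids + hull_less.sample_ids
    ref = ReferenceChemistry(sample_ids=ids, analytes=analytes.reset_index(drop=True))
    ref.grade = [
        grade_sample(
            ref.value(s, "tannin"), ref.value(s, "hemicellulose"), ref.value(s, "starch"),
            config.rules,
        )
        for s in ids
    ]
    return ref


def simulate_study(config: StudyConfig | None = None) -> AlignedDataset:
    """Simulate one scan format of the study as an :class:`AlignedDataset`.

    ``scan_format`` selects which scan is rendered: whole grains and whole
    grain flours cover all samples; hulled / hull-less flour scans cover only
    the corresponding morphology subset.
    """
    config = config or StudyConfig()
    if config.n_total < 8:
        raise ValueError("need at least 8 samples to partition 3:1 with >=2 validation")
    ref = _draw_study_chemistry(config)
    fmt = config.scan_format
    if fmt == "hulled_flour":
        keep = list(range(config.n_hulled))
    elif fmt == "hull_less_flour":
        keep = list(range(config.n_hulled, config.n_total))
    elif fmt in ("whole_grain", "whole_grain_flour"):
        keep = list(range(config.n_total))
    else:
        raise ValueError(f"unknown scan format {fmt!r}")
    ref = ref.subset(keep)
    library = default_band_library()
    fmt_index = ("whole_grain", "whole_grain_flour", "hulled_flour", "hull_less_flour").index(fmt)
    spectra = render_spectra(
        ref, library, config.effects,
        seed=np.random.default_rng((config.seed, 1 + fmt_index)).integers(2**31),
        sample_format=fmt,
    )
    return AlignedDataset(spectra=spectra, reference=ref)


def simulate_full_study(config: StudyConfig | None = None) -> dict[str, AlignedDataset]:
    """All four scan formats of the same simulated chemistry.

    The chemistry (and hence grading) is drawn once from ``config.seed``;
    each format renders its own spectra of the appropriate sample subset.
    """
    config = config or StudyConfig()
    datasets = {}
    for fmt in ("whole_grain", "whole_grain_flour", "hulled_flour", "hull_less_flour"):
        datasets[fmt] = simulate_study(replace(config, scan_format=fmt))
    return datasets
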