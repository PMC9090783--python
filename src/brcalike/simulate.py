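"""Synthetic-data generators for every input of the analysis chain.

The generators produce, with known ground truth: genomic bin grids with GC,
mappability, and blacklist annotations; class-specific segmental log2
copy-number signals; GC- and mappability-biased Poisson read counts;
randomized two-arm survival cohorts with marker-dependent treatment hazard
ratios; and paired continuous biomarker scores with a tunable concordance.

All randomness flows from a single integer seed through a named
`numpy.random.Generator`; no global RNG state is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import BIN_COLUMNS, normalize_chrom

BRCA1_LIKE = "BRCA1-like"
NON_BRCA1_LIKE = "non-BRCA1-like"
ARM_CONTROL = "T+CEF"
ARM_CAPECITABINE = "TX+CEX"


# ---------------------------------------------------------------------------
# genome / bin grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimGenome:
    """An autosome-only genome model for simulation.

    chrom_lengths maps autosome name -> length in bp; bin_size is the tiling
    resolution (20 kb by default, the resolution of shallow-WGS copy-number
    profiling).
    """

    chrom_lengths: dict
    bin_size: int = 20_000

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be non-empty")
        seen = set()
        for name, length in self.chrom_lengths.items():
            norm = normalize_chrom(name)  # rejects non-autosomes, names offender
            if norm in seen:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            seen.add(norm)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))


def make_bin_grid(
    genome: SimGenome,
    seed: int = 0,
    *,
    frac_low_mappability: float = 0.05,
    frac_high_mappability: float = 0.70,
    frac_blacklist: float = 0.02,
    gc_window: int = 25,
    gc_range: tuple = (0.30, 0.70),
) -> pd.DataFrame:
    """Tile a genome into half-open bins with GC/mappability/blacklist annotation.

    GC is a smoothed moving average (window `gc_window` bins) of uniform noise
    rescaled to `gc_range`, giving realistic spatial autocorrelation.
    Mappability is drawn from three strata: a `frac_low_mappability` fraction
    below 0.2, a `frac_high_mappability` fraction above 0.8, and the rest in
    between.  A `frac_blacklist` fraction of bins is flagged blacklisted.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for name, length in genome.chrom_lengths.items():
        chrom = normalize_chrom(name)
        starts = np.arange(0, length, genome.bin_size, dtype=np.int64)
        ends = np.minimum(starts + genome.bin_size, length)
        n = len(starts)

        raw = rng.uniform(size=n)
        w = min(gc_window, n)
        kernel = np.ones(w) / w
        smooth = np.convolve(raw, kernel, mode="same")
        lo, hi = smooth.min(), smooth.max()
        if hi > lo:
            gc = gc_range[0] + (smooth - lo) / (hi - lo) * (gc_range[1] - gc_range[0])
        else:
            gc = np.full(n, 0.5 * (gc_range[0] + gc_range[1]))

        stratum = rng.uniform(size=n)
        mapp = np.empty(n)
        low = stratum < frac_low_mappability
        high = stratum >= 1.0 - frac_high_mappability
        mid = ~(low | high)
        mapp[low] = rng.uniform(0.0, 0.2, low.sum())
        mapp[high] = rng.uniform(0.8, 1.0, high.sum())
        mapp[mid] = rng.uniform(0.2, 0.8, mid.sum())

        blacklist = rng.uniform(size=n) < frac_blacklist
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "gc": gc, "mappability": mapp, "blacklist": blacklist,
        }))
    return pd.concat(frames, ignore_index=True)[BIN_COLUMNS]


# ---------------------------------------------------------------------------
# copy-number signal
# ---------------------------------------------------------------------------

@dataclass
class CnvClassSpec:
    """Ground-truth copy-number signal model for one tumour class.

    aberration_regions are (chrom, start, end, mean_log2_shift) tuples: fixed
    shifts that characterize the class.  On top of these, random segmental
    shifts occur at `segment_rate` expected breakpoints per 100 Mb (segment
    levels drawn N(0, segment_shift_sd)), and per-bin Gaussian noise with sd
    `noise_sd` is added.
    """

    label: str
    aberration_regions: list = field(default_factory=list)
    segment_rate: float = 0.0
    noise_sd: float = 0.1
    segment_shift_sd: float = 0.3

    def __post_init__(self):
        if self.label not in (BRCA1_LIKE, NON_BRCA1_LIKE):
            raise ValueError(f"label must be {BRCA1_LIKE!r} or {NON_BRCA1_LIKE!r}, got {self.label!r}")
        if self.segment_rate < 0:
            raise ValueError("segment_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for region in self.aberration_regions:
            if not np.isfinite(region[3]):
                raise ValueError(f"non-finite mean_log2_shift in region {region!r}")


def simulate_profile(bins: pd.DataFrame, spec: CnvClassSpec, seed: int = 0):
    """Simulate the true per-bin log2 signal for one sample.

    Returns (signal, breakpoints): the per-bin log2 values (region shifts +
    random segmental shifts + Gaussian noise) and the list of (chrom, pos)
    breakpoints of the random segments.
    """
    if len(bins) == 0:
        raise ValueError("bins must be non-empty")
    rng = np.random.default_rng(seed)
    signal = np.zeros(len(bins), dtype=float)
    chrom = bins["chrom"].to_numpy()
    start = bins["start"].to_numpy()
    end = bins["end"].to_numpy()

    for region in spec.aberration_regions:
        rchrom, rstart, rend, shift = region
        rchrom = normalize_chrom(rchrom)
        hit = (chrom == rchrom) & (start < rend) & (end > rstart)
        if not hit.any():
            warnings.warn(f"aberration region {region!r} overlaps no bins; ignored")
            continue
        signal[hit] += shift

    breakpoints = []
    if spec.segment_rate > 0:
        for c in pd.unique(chrom):
            sel = chrom == c
            clen = int(end[sel].max())
            n_breaks = rng.poisson(spec.segment_rate * clen / 1e8)
            if n_breaks == 0:
                continue
            positions = np.sort(rng.integers(0, clen, size=n_breaks))
            bounds = np.concatenate(([0], positions, [clen]))
            levels = rng.normal(0.0, spec.segment_shift_sd, size=len(bounds) - 1)
            cstart = start[sel]
            seg_idx = np.searchsorted(bounds[1:-1], cstart, side="right")
            signal[sel] += levels[seg_idx]
            breakpoints.extend((c, int(p)) for p in positions)

    if spec.noise_sd > 0:
        signal += rng.normal(0.0, spec.noise_sd, size=len(bins))
    return signal, breakpoints


def simulate_counts(
    bins: pd.DataFrame,
    true_log2: np.ndarray,
    mean_depth: float,
    gc_bias: tuple = (0.0, 0.0, 0.0),
    seed: int = 0,
    overdispersion: float = 0.0,
) -> np.ndarray:
    """Draw per-bin read counts under GC and mappability bias.

    Expected count for bin i is
    ``mean_depth * 2**true_log2_i * mappability_i * exp(c0 + c1*gc + c2*gc**2)``
    and counts are Poisson with that mean (optionally Gamma-Poisson when
    `overdispersion` > 0, with variance mean*(1 + overdispersion*mean)).
    Blacklisted bins still receive counts — filtering them is the pipeline's
    job, not the sequencer's.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    true_log2 = np.asarray(true_log2, dtype=float)
    if len(true_log2) != len(bins):
        raise ValueError("true_log2 must be index-aligned with bins")
    rng = np.random.default_rng(seed)
    gc = bins["gc"].to_numpy()
    c0, c1, c2 = gc_bias
    mu = mean_depth * 2.0 ** true_log2 * bins["mappability"].to_numpy() * np.exp(c0 + c1 * gc + c2 * gc**2)
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        lam = rng.gamma(shape, mu * overdispersion)
        return rng.poisson(lam)
    return rng.poisson(mu)


def reads_from_counts(bins: pd.DataFrame, counts: np.ndarray, seed: int = 0) -> pd.DataFrame:
    """Scatter per-bin counts into individual read start positions (BED-like)."""
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts)
    chroms = np.repeat(bins["chrom"].to_numpy(), counts)
    starts = np.repeat(bins["start"].to_numpy(), counts)
    widths = np.repeat((bins["end"] - bins["start"]).to_numpy(), counts)
    pos = starts + rng.integers(0, widths)
    return pd.DataFrame({"chrom": chroms, "pos": pos})


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

#: Covariate level frequencies emulating an early-stage TNBC trial population.
DEFAULT_COVARIATE_DISTRIBUTIONS = {
    "who_ps": {"0": 0.845, "1": 0.155},
    "surgery": {"breast-conserving": 0.333, "mastectomy": 0.667},
    "axillary_surgery": {"dissection": 0.860, "sentinel": 0.140},
    "t_stage": {"pT1": 0.248, "pT2": 0.674, "pT3": 0.078},
    "nodes": {"<=3": 0.752, ">3": 0.248},
    "histology": {"ductal": 0.930, "lobular": 0.023, "other": 0.047},
    "grade": {"1": 0.008, "2": 0.116, "3": 0.876},
}


@dataclass
class SurvivalSimConfig:
    """Effect structure of a randomized two-arm, marker-stratified cohort.

    Recurrence times are exponential with hazard
    ``baseline_hazard * (hr_marker if marker-positive) * (arm HR within the
    marker stratum)``; death follows recurrence after an exponential delay;
    everyone is administratively censored at `admin_censor_time` years.
    Defaults emulate an adjuvant capecitabine trial in early-stage TNBC:
    treatment hazard ratio 0.23 among non-BRCA1-like (marker-negative)
    patients and 0.66 among BRCA1-like (marker-positive) patients, a
    prognostic marker HR of 0.74 for BRCA1-like status, a control-arm
    marker-negative recurrence hazard of 0.059/yr, and 10.7 years of
    follow-up.
    """

    n_control_neg: int = 32
    n_treat_neg: int = 29
    n_control_pos: int = 37
    n_treat_pos: int = 31
    baseline_hazard: float = 0.059
    hr_treatment_in_marker_neg: float = 0.23
    hr_treatment_in_marker_pos: float = 0.66
    hr_marker: float = 0.74
    admin_censor_time: float = 10.7
    post_recurrence_death_rate: float = 0.5
    seed: int = 0
    covariate_distributions: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_DISTRIBUTIONS.items()}
    )

    def __post_init__(self):
        for name in ("hr_treatment_in_marker_neg", "hr_treatment_in_marker_pos", "hr_marker"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n_control_neg", "n_treat_neg", "n_control_pos", "n_treat_pos"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")


def simulate_cohort(config: SurvivalSimConfig) -> pd.DataFrame:
    """Simulate one randomized cohort; returns a CohortRecord frame.

    Columns: id, arm, marker, time_to_recurrence, time_to_death,
    followup_time, plus the covariates age, who_ps, surgery,
    axillary_surgery, t_stage, nodes, histology, grade.  Event times beyond
    the administrative censoring horizon are recorded as missing.
    """
    rng = np.random.default_rng(config.seed)
    cells = [
        (ARM_CONTROL, NON_BRCA1_LIKE, config.n_control_neg, config.baseline_hazard),
        (ARM_CAPECITABINE, NON_BRCA1_LIKE, config.n_treat_neg,
         config.baseline_hazard * config.hr_treatment_in_marker_neg),
        (ARM_CONTROL, BRCA1_LIKE, config.n_control_pos,
         config.baseline_hazard * config.hr_marker),
        (ARM_CAPECITABINE, BRCA1_LIKE, config.n_treat_pos,
         config.baseline_hazard * config.hr_marker * config.hr_treatment_in_marker_pos),
    ]
    rows = []
    idx = 0
    cens = config.admin_censor_time
    for arm, marker, n, hazard in cells:
        if n == 0:
            continue
        recur = rng.exponential(1.0 / hazard, size=n)
        death = recur + rng.exponential(1.0 / config.post_recurrence_death_rate, size=n)
        for i in range(n):
            idx += 1
            rows.append({
                "id": f"P{idx:05d}",
                "arm": arm,
                "marker": marker,
                "time_to_recurrence": recur[i] if recur[i] <= cens else np.nan,
                "time_to_death": death[i] if death[i] <= cens else np.nan,
                "followup_time": cens,
            })
    cohort = pd.DataFrame(rows)
    n_total = len(cohort)
    cohort["age"] = np.clip(np.round(rng.normal(52.5, 9.0, size=n_total)), 25, 64).astype(int)
    for name, dist in config.covariate_distributions.items():
        levels = list(dist)
        probs = np.asarray([dist[k] for k in levels], dtype=float)
        probs = probs / probs.sum()
        cohort[name] = rng.choice(levels, size=n_total, p=probs)
    return cohort


# ---------------------------------------------------------------------------
# paired biomarker scores
# ---------------------------------------------------------------------------

def _bvn_cdf(z: float, rho: float) -> float:
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf([z, z]))


def _concordance_of_rho(rho: float, p: float) -> float:
    # P(both below) + P(both above) when both margins are cut at quantile p
    z = stats.norm.ppf(p)
    both_low = _bvn_cdf(z, rho)
    return 1.0 - 2.0 * p + 2.0 * both_low


def simulate_paired_scores(
    n: int,
    target_concordance: float,
    cutoff_a: float = 0.63,
    seed: int = 0,
    frac_below_cutoff: float | None = None,
    score_b_scale: tuple = (0.4, 1.82),
) -> pd.DataFrame:
    """Simulate paired biomarker scores with a target binary concordance.

    Latent scores are a Gaussian copula on ranks: (Z1, Z2) bivariate normal
    with the correlation chosen by a root-finder so that, after cutting
    score_a at `cutoff_a` and score_b at the matching percentile, the
    concordant fraction converges to `target_concordance`.  score_a lies in
    [0, 1]; score_b is on an arbitrary positive log-normal-like scale.
    `frac_below_cutoff` fixes P(score_a < cutoff_a) (default: uniform
    scores, so it equals cutoff_a).
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if not (0.5 <= target_concordance <= 1.0):
        raise ValueError("target_concordance must be in [0.5, 1]")
    p = cutoff_a if frac_below_cutoff is None else frac_below_cutoff
    if not (0.0 < p < 1.0):
        raise ValueError("fraction below cutoff must be in (0, 1)")

    rng = np.random.default_rng(seed)
    mu_shift = stats.norm.ppf(cutoff_a) - stats.norm.ppf(p)
    z1 = rng.normal(size=n)
    b_sd, b_loc = score_b_scale

    if target_concordance >= 1.0:
        z2 = z1.copy()  # comonotone: ranks coincide exactly
    else:
        lo, hi = -0.999, 0.9999
        f = lambda r: _concordance_of_rho(r, p) - target_concordance
        if f(hi) < 0 or f(lo) > 0:
            raise ValueError(
                f"target concordance {target_concordance} unreachable at marginal fraction {p}"
            )
        rho = optimize.brentq(f, lo, hi, xtol=1e-10)
        z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.normal(size=n)

    score_a = stats.norm.cdf(z1 + mu_shift)
    score_b = np.exp(b_sd * z2 + b_loc)
    return pd.DataFrame({
        "sample_id": [f"S{i + 1:05d}" for i in range(n)],
        "score_a": score_a,
        "score_b": score_b,
    })


def exact_concordance_pairs(
    n: int,
    n_concordant: int,
    cutoff_a: float = 0.63,
    n_below_cutoff: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Construct paired scores with an exact concordant count.

    Exactly `n_below_cutoff` score_a values fall strictly below `cutoff_a`
    (default: round(cutoff_a * n)), and the `n - n_concordant` discordant
    pairs are split as evenly as possible between the two directions, so the
    marginal-matched dichotomization yields exactly `n_concordant` agreeing
    calls.  Used to rebuild published 2x2 concordance tables synthetically.
    """
    if not (0 <= n_concordant <= n):
        raise ValueError("n_concordant must be between 0 and n")
    n_low = round(cutoff_a * n) if n_below_cutoff is None else n_below_cutoff
    if not (0 < n_low < n):
        raise ValueError("n_below_cutoff must leave both classes non-empty")
    n_disc = n - n_concordant
    if n_disc % 2 != 0:
        raise ValueError("discordant count must be even to split equally in both directions")
    d_each = n_disc // 2
    if d_each > min(n_low, n - n_low):
        raise ValueError("too many discordant pairs for the marginal split")

    rng = np.random.default_rng(seed)
    score_a = np.empty(n)
    score_a[:n_low] = rng.uniform(0.02, cutoff_a - 0.01, size=n_low)
    score_a[n_low:] = rng.uniform(cutoff_a + 0.005, 0.99, size=n - n_low)

    # b-ranks: the n_low lowest go to (a-low minus d_each swapped out) plus
    # d_each a-high samples swapped in
    low_a = np.arange(n_low)
    high_a = np.arange(n_low, n)
    swapped_low_a = rng.choice(low_a, size=d_each, replace=False)
    swapped_high_a = rng.choice(high_a, size=d_each, replace=False)
    low_b_members = np.concatenate([np.setdiff1d(low_a, swapped_low_a), swapped_high_a])
    high_b_members = np.setdiff1d(np.arange(n), low_b_members)

    b_values = np.sort(rng.uniform(2.0, 12.0, size=n))
    score_b = np.empty(n)
    score_b[rng.permutation(low_b_members)] = b_values[:n_low]
    score_b[rng.permutation(high_b_members)] = b_values[n_low:]

    perm = rng.permutation(n)
    return pd.DataFrame({
        "sample_id": [f"S{i + 1:05d}" for i in range(n)],
        "score_a": score_a[perm],
        "score_b": score_b[perm],
    })
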