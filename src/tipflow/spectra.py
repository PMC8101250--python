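"""Site frequencies, folded SFS, insertion dating, and substitution-rate estimation.

Frequencies use the number of informative (non-NA) genomes at each site as the
denominator.  The folded site frequency spectrum is a minor-allele-frequency
histogram in equal bins on [0, 0.5], written in a layout usable as input to
DFE-estimation software.  Insertion ages come from the highest pairwise SNP
divergence among carriers in a 70-kb window around the site, converted to
generations with the base mutation rate.  The TE insertion substitution rate
is the no-intercept TIP-per-SNP regression slope over closely related
accessions multiplied by the genome-wide SNP substitution rate; comparing the
short-term slope with the (selection-rescaled) long-term slope yields the
fraction of insertions eventually eliminated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MU = 7e-9
DEFAULT_SNP_RATE = 0.2511
DEFAULT_WINDOW = 70_000
CLOSE_PAIR_SNP_THRESHOLD = 500
VERY_RECENT_FREQ = 0.002
VERY_RECENT_AGE = 1000.0


def site_frequencies(matrix) -> pd.DataFrame:
    """Per-site frequency, MAF and private flag from a genotype matrix."""
    s = matrix.states.to_numpy()
    informative = np.sum(~np.isnan(s), axis=1)
    if np.any(informative == 0):
        raise ValueError("site with zero informative genomes; filter first")
    carriers = np.nansum(s, axis=1).astype(int)
    freq = carriers / informative
    return pd.DataFrame({
        "informative": informative,
        "n_carriers": carriers,
        "frequency": freq,
        "maf": np.minimum(freq, 1.0 - freq),
        "private": carriers == 1,
    }, index=matrix.states.index)


@dataclass
class SfsTable:
    category: str
    edges: np.ndarray       # n_bins + 1 edges on [0, 0.5]
    counts: np.ndarray

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


def folded_sfs(frequencies, category: str = "TIP", n_bins: int = 500) -> SfsTable:
    """Folded SFS: histogram of min(f, 1-f) in equal bins on [0, 0.5].

    The MAF is snapped at 12 decimals before binning so that folding is exactly
    symmetric (f and 1-f always land in the same bin) despite the one-ulp
    difference between f and 1-(1-f) in floating point.
    """
    f = np.asarray(frequencies, dtype=float)
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    if f.size == 0:
        return SfsTable(category, edges, np.zeros(n_bins, dtype=int))
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("frequencies must lie in (0, 1)")
    maf = np.round(np.minimum(f, 1.0 - f), 12)
    counts, _ = np.histogram(maf, bins=edges)
    return SfsTable(category, edges, counts)


def write_sfs(tables, path) -> None:
    """Write folded SFS tables: category header line, then the bin counts."""
    if isinstance(tables, SfsTable):
        tables = [tables]
    with open(path, "w") as fh:
        fh.write(f"{len(tables)}\n")
        for t in tables:
            fh.write(f"{t.category} {len(t.counts)}\n")
            fh.write(" ".join(str(int(c)) for c in t.counts) + "\n")


def estimate_tip_age(max_snps, window_length: int = DEFAULT_WINDOW,
                     mu: float = DEFAULT_MU, two_lineages: bool = False):
    """Age in generations from the max pairwise SNP count among carriers.

    age = (max_snps / window_length) / mu; with ``two_lineages`` the divergence
    is halved to account for mutations accumulating on both lineages.
    """
    if window_length <= 0:
        raise ValueError("window length must be positive")
    age = (np.asarray(max_snps, dtype=float) / window_length) / mu
    if two_lineages:
        age = age / 2.0
    return age


def classify_very_recent(freqs: pd.DataFrame, ages: pd.Series | dict | None = None,
                         matrix=None,
                         freq_threshold: float = VERY_RECENT_FREQ,
                         age_threshold: float = VERY_RECENT_AGE,
                         min_family_total: int = 20):
    """Very recent TIPs: frequency below threshold AND (private OR young).

    Returns the very-recent site index, per-accession carried counts (when a
    matrix is given) and per-family counts restricted to families with more
    than ``min_family_total`` TIPs overall.
    """
    ages = pd.Series(dtype=float) if ages is None else pd.Series(ages)
    age = ages.reindex(freqs.index)
    young = age.notna() & (age < age_threshold)
    very_recent = (freqs["frequency"] < freq_threshold) & (freqs["private"] | young)
    vr_sites = freqs.index[very_recent]

    per_accession = None
    per_family = None
    if matrix is not None:
        vr_states = matrix.states.loc[vr_sites]
        per_accession = (vr_states == 1.0).sum(axis=0).astype(int)
        fam = matrix.sites["family"]
        totals = fam.value_counts()
        eligible = totals.index[totals > min_family_total]
        fam_vr = fam.loc[vr_sites]
        per_family = (
            fam_vr[fam_vr.isin(eligible)].value_counts()
            .reindex(eligible, fill_value=0).astype(int)
        )
    return vr_sites, per_accession, per_family


def fit_no_intercept_slope(snp_diff, tip_diff) -> tuple[float, float]:
    """No-intercept least squares: slope = sum(xy)/sum(x^2), with its SE."""
    x = np.asarray(snp_diff, dtype=float)
    y = np.asarray(tip_diff, dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("undefined slope: all SNP differences are zero")
    slope = float(np.sum(x * y)) / sxx
    n = len(x)
    if n > 1:
        rss = float(np.sum((y - slope * x) ** 2))
        se = np.sqrt(rss / (n - 1) / sxx)
    else:
        se = float("nan")
    return slope, se


@dataclass
class RateEstimate:
    slope_close: float
    slope_close_se: float
    slope_all: float
    slope_all_se: float
    kappa: float
    substitution_rate: float
    substitution_rate_se: float
    elimination_fraction: float
    elimination_fraction_se: float


def estimate_rates(pairs: pd.DataFrame,
                   snp_rate: float = DEFAULT_SNP_RATE) -> RateEstimate:
    """Substitution rate and elimination fraction from pairwise divergence.

    ``kappa`` (selection scaling) is the ratio of synonymous-SNP fractions in
    distant vs close pairs; multiplying observed long-term SNP divergence by
    kappa gives its neutral equivalent.  The elimination fraction is
    1 - slope_all / (kappa * slope_close), clipped to [0, 1).
    """
    close = pairs.loc[pairs["pair_class"] == "close"]
    allp = pairs.loc[pairs["pair_class"] == "all"]
    if close.empty or allp.empty:
        raise ValueError("both 'close' and 'all' pair classes are required")
    slope_close, se_close = fit_no_intercept_slope(close["snp_diff"], close["tip_diff"])
    slope_all, se_all = fit_no_intercept_slope(allp["snp_diff"], allp["tip_diff"])
    syn_close = close["syn_snp_diff"].sum() / close["snp_diff"].sum()
    syn_all = allp["syn_snp_diff"].sum() / allp["snp_diff"].sum()
    if syn_close <= 0:
        raise ValueError("kappa undefined: no synonymous SNPs among close pairs")
    kappa = float(syn_all / syn_close)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    subst = slope_close * snp_rate
    subst_se = se_close * snp_rate
    denom = kappa * slope_close
    raw = 1.0 - slope_all / denom if denom > 0 else float("nan")
    elim = float(np.clip(raw, 0.0, np.nextafter(1.0, 0.0)))
    # delta method on the slope ratio, kappa treated as fixed
    if denom > 0 and np.isfinite(se_all) and np.isfinite(se_close):
        elim_se = float(np.sqrt(
            (se_all / denom) ** 2
            + (slope_all * se_close / (kappa * slope_close ** 2)) ** 2
        ))
    else:
        elim_se = float("nan")
    return RateEstimate(
        slope_close=slope_close, slope_close_se=se_close,
        slope_all=slope_all, slope_all_se=se_all,
        kappa=kappa,
        substitution_rate=subst, substitution_rate_se=subst_se,
        elimination_fraction=elim, elimination_fraction_se=elim_se,
    )
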