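"""Synthetic cohorts with the statistical structure of a species-wide TE survey.

Generates everything the downstream pipeline consumes, with known ground truth:
a structured accession panel (genetic groups, kinship, a large-effect modifier
allele of the RdDM pathway), a frequency-skewed TIP genotype matrix with
per-accession read-coverage evidence (including planted filter violations),
pairwise SNP/TIP divergence consistent with a tunable transposition rate and
retention probability, group-correlated climate gradients (current and future
epochs), per-site local-divergence windows for insertion dating, and an
expression matrix with carrier-shifted genes.

Everything is driven by one :class:`CohortConfig`; identical config + seed
yields a bit-identical cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyping import CALL_COLUMNS, TipGenotypeMatrix

TEMP_BIO = [f"BIO{i:02d}" for i in range(1, 12)]
PRECIP_BIO = [f"BIO{i:02d}" for i in range(12, 20)]
BIO_VARS = TEMP_BIO + PRECIP_BIO

# plausible raw scales so z-scoring is non-trivial (temperature in degC x10
# style summaries and precipitation in mm, loosely WorldClim-like)
_BIO_MEAN = np.array([9.0, 8.5, 35.0, 600.0, 22.0, -2.0, 24.0, 10.0, 4.0, 16.0, 2.0,
                      650.0, 80.0, 30.0, 40.0, 210.0, 110.0, 190.0, 160.0])
_BIO_SD = np.array([4.0, 1.5, 8.0, 150.0, 4.5, 5.0, 4.0, 5.0, 6.0, 4.0, 5.0,
                    250.0, 30.0, 12.0, 15.0, 80.0, 50.0, 80.0, 70.0])

FAMILY_SUPERFAMILY = {
    "ATCOPIA93": "COPIA", "ATCOPIA78": "COPIA", "ATCOPIA21": "COPIA",
    "ATGP3": "GYPSY", "ATLANTYS2": "GYPSY",
    "VANDAL21": "MuDR", "ATMU5": "MuDR", "ATMU10": "MuDR",
    "ATHAT6": "hAT", "TAG1": "hAT",
    "ATLINE1_6": "LINE",
    "ATREP3": "HELITRON",
}
MOBILE_FAMILIES = [f for f, s in FAMILY_SUPERFAMILY.items() if s != "HELITRON"]

TRUTH_SCHEMA_VERSION = 1


@dataclass
class CohortConfig:
    """Generating parameters for one synthetic cohort.

    ``base_rate`` is the expected number of very recent (unpurged) insertions
    per non-carrier genome; carriers of the modifier allele multiply it by
    ``modifier_effect`` (default 3.4, i.e. a 240% increase), and z-scored
    bio-variables act through ``env_effects`` (fixed) and ``gxe_effects``
    (modifier interactions) on the log scale.  ``mu`` is the per-site
    per-generation base mutation rate and ``snp_rate`` the genome-wide SNP
    substitution rate used to convert TIP-per-SNP slopes into rates.
    """

    n_accessions: int = 300
    n_groups: int = 3
    kinship_strength: float = 4.0
    base_rate: float = 3.0
    retention_prob: float = 0.1
    modifier_effect: float = 3.4
    modifier_freq: float = 0.25
    gxe_effects: dict = field(default_factory=dict)
    env_effects: dict = field(default_factory=dict)
    mu: float = 7e-9
    snp_rate: float = 0.2511
    seed: int = 0

    # toy genome / annotation
    genome_length: int = 1_000_000
    n_genes: int = 120
    centromere_fraction: float = 0.1

    # TIP matrix
    n_background_sites: int = 400
    sfs_skew: float = 1.6
    absence_fraction: float = 0.15
    na_rate: float = 0.02
    depth: float = 10.0
    frac_low_dp: float = 0.02
    frac_low_informative: float = 0.02
    frac_het_like: float = 0.02
    frac_fragmented: float = 0.3
    frac_ancestral: float = 0.1
    n_helitron_presence: int = 4
    low_informative_keep: int = 10
    n_young_shared: int = 5
    age_scale: float = 2e5

    # divergence pairs
    slope_true: float = 0.304
    close_snp_mean: float = 200.0
    distant_snp_mean: float = 20000.0
    syn_frac_close: float = 0.25
    syn_enrichment: float = 1.3
    n_close_pairs: int = 300
    n_distant_pairs: int = 300

    # climate
    climate_group_sd: float = 1.2
    warming_shift: float = 2.8
    precip_change: float = -0.12

    # expression
    expr_effect_fraction: float = 0.25
    expr_effect: float = 0.25
    expr_noise_sd: float = 0.2

    def validate(self) -> None:
        if self.n_accessions < 2:
            raise ValueError("invalid config: n_accessions must be >= 2")
        if not (0 < self.retention_prob <= 1):
            raise ValueError("invalid config: retention_prob must be in (0, 1]")
        for name in ("kinship_strength", "base_rate", "modifier_effect",
                     "mu", "snp_rate", "slope_true"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config: {name} must be >= 0")
        if self.n_groups < 1:
            raise ValueError("invalid config: n_groups must be >= 1")
        unknown = (set(self.gxe_effects) | set(self.env_effects)) - set(BIO_VARS)
        if unknown:
            raise ValueError(f"invalid config: unknown bio-variables {sorted(unknown)}")


@dataclass
class SyntheticCohort:
    panel: pd.DataFrame
    kinship: np.ndarray
    tips: TipGenotypeMatrix
    candidates: pd.DataFrame
    pairs: pd.DataFrame
    climate: pd.DataFrame
    expression: pd.DataFrame
    genes: "GeneAnnotation"
    windows: pd.DataFrame
    truth: dict


# --------------------------------------------------------------------- panel

def simulate_panel(config: CohortConfig, rng: np.random.Generator):
    """Accession panel with genetic groups, kinship PCs, modifier allele, geography."""
    n, g = config.n_accessions, config.n_groups
    groups = np.arange(n) % g
    d = 8
    centers = rng.normal(size=(g, d)) * config.kinship_strength
    latent = centers[groups] + rng.normal(size=(n, d))
    kinship = np.corrcoef(latent)
    vals, vecs = np.linalg.eigh(kinship)
    order = np.argsort(vals)[::-1][:3]
    pcs = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    # deterministic sign: largest-magnitude coordinate positive
    for j in range(pcs.shape[1]):
        k = np.argmax(np.abs(pcs[:, j]))
        if pcs[k, j] < 0:
            pcs[:, j] *= -1
    modifier = (rng.random(n) < config.modifier_freq).astype(int)
    if 0 < config.modifier_freq < 1:
        if modifier.sum() == 0:
            modifier[rng.integers(n)] = 1
        elif modifier.sum() == n:
            modifier[rng.integers(n)] = 0
    geo_centers = rng.uniform([35.0, -10.0], [62.0, 40.0], size=(g, 2))
    geo = geo_centers[groups] + rng.normal(0, 1.5, size=(n, 2))
    panel = pd.DataFrame({
        "accession": [f"acc{i:04d}" for i in range(n)],
        "group": groups,
        "PC1": pcs[:, 0], "PC2": pcs[:, 1], "PC3": pcs[:, 2],
        "modifier": modifier,
        "latitude": geo[:, 0], "longitude": geo[:, 1],
    })
    return panel, kinship


# ------------------------------------------------------------------- climate

def simulate_climate(panel: pd.DataFrame, config: CohortConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Current and future climate tables with group-correlated gradients."""
    n = len(panel)
    g = config.n_groups
    centers = rng.normal(size=(g, 19)) * config.climate_group_sd
    z = centers[panel["group"].to_numpy()] + rng.normal(size=(n, 19))
    current = _BIO_MEAN + _BIO_SD * z
    future = current.copy()
    temp_idx = [BIO_VARS.index(b) for b in TEMP_BIO]
    prec_idx = [BIO_VARS.index(b) for b in PRECIP_BIO]
    future[:, temp_idx] += config.warming_shift + rng.normal(0, 0.3, size=(n, len(temp_idx)))
    future[:, prec_idx] *= (1.0 + config.precip_change
                            + rng.normal(0, 0.02, size=(n, len(prec_idx))))
    rows = []
    for epoch, mat in (("current", current), ("future", future)):
        df = pd.DataFrame(mat, columns=BIO_VARS)
        df.insert(0, "epoch", epoch)
        df.insert(0, "accession", panel["accession"].to_numpy())
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def _current_z(climate: pd.DataFrame) -> pd.DataFrame:
    cur = climate.loc[climate["epoch"] == "current"].set_index("accession")[BIO_VARS]
    return (cur - cur.mean()) / cur.std(ddof=0)


def very_recent_rates(panel: pd.DataFrame, climate: pd.DataFrame,
                      config: CohortConfig) -> np.ndarray:
    """Expected very-recent insertion count per accession (log-link Poisson mean)."""
    z = _current_z(climate).loc[panel["accession"]].to_numpy()
    m = panel["modifier"].to_numpy()
    eta = np.log(max(config.base_rate, 1e-300)) * np.ones(len(panel))
    if config.base_rate == 0:
        return np.zeros(len(panel))
    eta += np.log(config.modifier_effect) * m
    for b, beta in config.env_effects.items():
        eta += beta * z[:, BIO_VARS.index(b)]
    for b, beta in config.gxe_effects.items():
        eta += beta * z[:, BIO_VARS.index(b)] * m
    return np.exp(eta)


# ---------------------------------------------------------------- annotation

def simulate_genes(config: CohortConfig, rng: np.random.Generator):
    """Non-overlapping genes with exon/intron/UTR substructure on a 1-chromosome toy genome."""
    from .impact import GeneAnnotation

    genes, features = [], []
    cursor = int(0.01 * config.genome_length)
    i = 0
    while i < config.n_genes:
        cursor += int(rng.integers(500, 3000))
        glen = int(rng.integers(1500, 4000))
        if cursor + glen >= config.genome_length:
            break
        gid = f"gene{i:04d}"
        start, end = cursor, cursor + glen
        strand = "+" if rng.random() < 0.5 else "-"
        utr5, utr3 = 150, 200
        body_start, body_end = start + utr5, end - utr3
        n_ex = int(rng.integers(1, 5))
        bounds = np.sort(rng.choice(
            np.arange(body_start + 50, body_end - 50), size=2 * (n_ex - 1), replace=False
        )) if n_ex > 1 else np.array([], dtype=int)
        edges = np.concatenate([[body_start], bounds, [body_end]])
        if strand == "+":
            features.append((gid, "five_prime_UTR", start, start + utr5))
            features.append((gid, "three_prime_UTR", end - utr3, end))
        else:
            features.append((gid, "three_prime_UTR", start, start + utr3))
            features.append((gid, "five_prime_UTR", end - utr5, end))
        for k in range(0, len(edges) - 1):
            kind = "exon" if k % 2 == 0 else "intron"
            features.append((gid, kind, int(edges[k]), int(edges[k + 1])))
        genes.append({
            "gene_id": gid, "chrom": "chr1", "start": start, "end": end,
            "strand": strand,
            "pseudogene": bool(rng.random() < 0.05),
            "essential": bool(rng.random() < 0.10),
            "pnps": float(rng.lognormal(-1.0, 0.5)),
        })
        cursor = end
        i += 1
    gdf = pd.DataFrame(genes).set_index("gene_id")
    fdf = pd.DataFrame(features, columns=["gene_id", "kind", "start", "end"])
    return GeneAnnotation(genes=gdf, features=fdf)


# -------------------------------------------------------------------- TIPs

def _skewed_carrier_counts(n_sites: int, n: int, skew: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Carrier counts k in 1..n with P(k) proportional to k**-skew (rare-skewed)."""
    k = np.arange(1, n + 1, dtype=float)
    if np.isinf(skew):
        p = np.zeros(n)
        p[0] = 1.0
    else:
        p = k ** (-skew)
        p /= p.sum()
    return rng.choice(np.arange(1, n + 1), size=n_sites, p=p)


def simulate_tip_data(panel: pd.DataFrame, genes, climate: pd.DataFrame,
                      config: CohortConfig, rng: np.random.Generator):
    """TIP sites, true genotype matrix, coverage-evidence candidate calls, windows.

    Background (standing) sites get carrier counts from the configured skew
    law; very recent sites are private, one per transposition event, with the
    per-accession event count Poisson around the modifier/GxE-modulated rate.
    Configurable fractions of background sites violate each downstream filter
    (recorded in truth for planted-violation tests).
    """
    n = len(panel)
    acc = panel["accession"].to_numpy()
    L = config.genome_length

    lam = very_recent_rates(panel, climate, config)
    vr_counts = rng.poisson(lam)

    n_bg = config.n_background_sites
    n_abs = int(round(config.absence_fraction * n_bg))
    n_pres_bg = n_bg - n_abs

    records = []   # (var_class, family, carriers_array, label, true_age, very_recent)
    k_bg = _skewed_carrier_counts(n_pres_bg, n, config.sfs_skew, rng)
    fams = list(FAMILY_SUPERFAMILY)
    mobile = MOBILE_FAMILIES

    # planted violation labels among background presence sites
    labels = np.array(["clean"] * n_pres_bg, dtype=object)
    n_low_dp = max(1, int(config.frac_low_dp * n_pres_bg)) if config.frac_low_dp > 0 else 0
    n_low_inf = max(1, int(config.frac_low_informative * n_pres_bg)) if config.frac_low_informative > 0 else 0
    n_het = max(1, int(config.frac_het_like * n_pres_bg)) if config.frac_het_like > 0 else 0
    pool = rng.permutation(n_pres_bg)
    labels[pool[:n_low_dp]] = "low_dp"
    labels[pool[n_low_dp:n_low_dp + n_low_inf]] = "low_informative"
    labels[pool[n_low_dp + n_low_inf:n_low_dp + n_low_inf + n_het]] = "het_like"

    for j in range(n_pres_bg):
        k = int(k_bg[j])
        carriers = rng.choice(n, size=k, replace=False)
        fam = mobile[int(rng.integers(len(mobile)))]
        age = float((k / n) * config.age_scale * rng.lognormal(0.0, 0.3))
        records.append(("presence", fam, carriers, labels[j], age, False))

    # young shared rare sites (exercise the age branch of very-recent calls)
    for _ in range(config.n_young_shared):
        carriers = rng.choice(n, size=2, replace=False)
        fam = mobile[int(rng.integers(len(mobile)))]
        age = float(rng.uniform(100, 900))
        records.append(("presence", fam, carriers, "clean", age, False))

    # HELITRON presence sites (blacklist exercise)
    for _ in range(config.n_helitron_presence):
        k = int(_skewed_carrier_counts(1, n, config.sfs_skew, rng)[0])
        carriers = rng.choice(n, size=k, replace=False)
        records.append(("presence", "ATREP3", carriers, "helitron_presence",
                        float(rng.uniform(1e3, 1e5)), False))

    # absence sites; configurable fractions flagged fragmented / ancestral
    for _ in range(n_abs):
        k = int(_skewed_carrier_counts(1, n, config.sfs_skew, rng)[0])
        carriers = rng.choice(n, size=k, replace=False)
        fam = fams[int(rng.integers(len(fams)))]
        u = rng.random()
        if u < config.frac_fragmented:
            lab = "fragmented"
        elif u < config.frac_fragmented + config.frac_ancestral:
            lab = "ancestral"
        else:
            lab = "clean"
        records.append(("absence", fam, carriers, lab,
                        float(rng.uniform(1e3, 1e5)), False))

    # very recent private presence sites, one per event
    for i in np.flatnonzero(vr_counts):
        for _ in range(int(vr_counts[i])):
            fam = mobile[int(rng.integers(len(mobile)))]
            records.append(("presence", fam, np.array([i]), "clean",
                            float(rng.uniform(1, 50)), True))

    S = len(records)
    # sites on a coarse grid so distinct truth sites never merge accidentally
    n_slots = L // 250
    if S > n_slots:
        raise ValueError("too many TIP sites for the configured genome length")
    slots = np.sort(rng.choice(n_slots, size=S, replace=False))
    positions = slots * 250 + rng.integers(60, 190, size=S)
    cen_lo = int((0.5 - config.centromere_fraction / 2) * L)
    cen_hi = int((0.5 + config.centromere_fraction / 2) * L)

    carrier_mat = np.zeros((S, n), dtype=bool)
    for s, rec in enumerate(records):
        carrier_mat[s, rec[2]] = True

    # coverage evidence
    depth = config.depth
    flank = np.maximum(rng.poisson(depth, size=(S, n)), 1).astype(float)
    pos_cov = np.where(carrier_mat, rng.poisson(depth, size=(S, n)),
                       rng.poisson(0.02, size=(S, n))).astype(float)
    neg_cov = np.where(carrier_mat, rng.poisson(0.5, size=(S, n)),
                       rng.poisson(depth, size=(S, n))).astype(float)
    site_cov = np.where(carrier_mat, rng.poisson(0.25 * depth, size=(S, n)),
                        rng.poisson(depth, size=(S, n))).astype(float)
    na_mask = rng.random((S, n)) < config.na_rate

    for s, rec in enumerate(records):
        lab, carr = rec[3], rec[2]
        if lab == "low_dp":
            pos_cov[s, carr] = rng.integers(1, 3, size=len(carr))
        elif lab == "low_informative":
            keep = rng.choice(n, size=min(config.low_informative_keep, n), replace=False)
            mask = np.ones(n, dtype=bool)
            mask[keep] = False
            na_mask[s, mask] = True
        elif lab == "het_like":
            p = rng.poisson(depth, size=len(carr)) + 3
            pos_cov[s, carr] = p
            neg_cov[s, carr] = p + rng.poisson(2, size=len(carr))
    # ensure planted carriers are never wiped out by the NA mask
    na_mask[carrier_mat & (pos_cov >= 3)] = False
    pos_cov[na_mask] = 0.0
    neg_cov[na_mask] = 0.0
    site_cov[na_mask] = 0.0
    flank[na_mask] = 1.0

    site_ids = [f"SITE{s:06d}" for s in range(S)]
    sites = pd.DataFrame({
        "chrom": "chr1",
        "pos": positions,
        "start": positions - 40,
        "end": positions + 40,
        "family": [r[1] for r in records],
        "superfamily": [FAMILY_SUPERFAMILY[r[1]] for r in records],
        "var_class": [r[0] for r in records],
        "fragmented_ref": [r[3] == "fragmented" for r in records],
        "ancestral": [r[3] == "ancestral" for r in records],
    }, index=pd.Index(site_ids, name="site_id"))
    truth_sites = sites.assign(
        label=[r[3] for r in records],
        true_age=[r[4] for r in records],
        very_recent=[r[5] for r in records],
        n_true_carriers=carrier_mat.sum(axis=1),
    )

    # true genotype matrix: clean sites only, NA where evidence was wiped
    clean = truth_sites["label"].to_numpy() == "clean"
    states = np.where(carrier_mat, 1.0, 0.0)
    states[na_mask] = np.nan
    tips = TipGenotypeMatrix(
        sites=sites.loc[clean].copy(),
        states=pd.DataFrame(states[clean], index=sites.index[clean], columns=acc),
        evidence={"pos": pos_cov[clean], "neg": neg_cov[clean]},
        provenance=[{"stage": "synthetic_truth", "removed": 0,
                     "remaining": int(clean.sum())}],
    )
    tips.recompute_stats()

    # candidate calls: one row per accession per site (carriers jittered)
    jit = np.where(carrier_mat, rng.integers(-10, 11, size=(S, n)), 0)
    start = (positions[:, None] - 40 + jit).ravel()
    end = (positions[:, None] + 40 + jit).ravel()
    split_total = rng.binomial(pos_cov.astype(int), 0.6)
    split_left = rng.binomial(split_total, 0.5)
    disc_total = pos_cov.astype(int) - split_total
    disc_left = rng.binomial(disc_total, 0.5)
    calls = pd.DataFrame({
        "sample": np.tile(acc, S),
        "chrom": "chr1",
        "start": start,
        "end": end,
        "family": np.repeat(sites["family"].to_numpy(), n),
        "superfamily": np.repeat(sites["superfamily"].to_numpy(), n),
        "var_class": np.repeat(sites["var_class"].to_numpy(), n),
        "split_left": split_left.ravel(),
        "split_right": (split_total - split_left).ravel(),
        "disc_left": disc_left.ravel(),
        "disc_right": (disc_total - disc_left).ravel(),
        "pos_cov": pos_cov.ravel(),
        "neg_cov": neg_cov.ravel(),
        "site_cov": site_cov.ravel(),
        "flank_cov": flank.ravel(),
        "library": np.tile([f"L{i:04d}" for i in range(n)], S),
        "centromeric": np.repeat((positions >= cen_lo) & (positions < cen_hi), n),
        "spans_donor": False,
        "fragmented_ref": np.repeat(sites["fragmented_ref"].to_numpy(), n),
        "ancestral": np.repeat(sites["ancestral"].to_numpy(), n),
    })[CALL_COLUMNS]

    # dating windows for shared sites: one-lineage Poisson(L_window * mu * age)
    shared = carrier_mat.sum(axis=1) >= 2
    wlen = 70_000
    ages = truth_sites["true_age"].to_numpy()
    max_snps = rng.poisson(wlen * config.mu * ages[shared])
    windows = pd.DataFrame({
        "site_id": sites.index[shared],
        "half_width": 35_000,
        "max_snps": max_snps,
        "n_pairs": [int(k * (k - 1) / 2) for k in carrier_mat.sum(axis=1)[shared]],
    })

    vr_truth = pd.DataFrame({
        "accession": acc,
        "lambda": lam,
        "very_recent_count": vr_counts,
    })
    return tips, calls, truth_sites, windows, vr_truth


# -------------------------------------------------------------- divergence

def simulate_divergence_pairs(panel: pd.DataFrame, config: CohortConfig,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Pairwise SNP / synonymous-SNP / TIP difference counts.

    Close pairs (same genetic group, < 500 SNPs apart) accumulate TIP
    differences at ``slope_true`` per SNP.  Distant pairs are attenuated by
    ``retention_prob`` after converting observed SNP divergence to its neutral
    equivalent (x ``syn_enrichment``), so the downstream estimator's
    elimination fraction has expectation 1 - retention_prob.
    """
    n = len(panel)
    groups = panel["group"].to_numpy()
    slope = config.slope_true if config.base_rate > 0 else 0.0

    def sample_pairs(m, same_group):
        a = rng.integers(n, size=3 * m + 8)
        b = rng.integers(n, size=3 * m + 8)
        ok = a != b
        if same_group and config.n_groups > 1:
            ok &= groups[a] == groups[b]
        elif not same_group and config.n_groups > 1:
            ok &= groups[a] != groups[b]
        a, b = a[ok], b[ok]
        while len(a) < m:
            a2 = rng.integers(n, size=2 * m)
            b2 = rng.integers(n, size=2 * m)
            ok = a2 != b2
            if config.n_groups > 1:
                ok &= (groups[a2] == groups[b2]) == same_group
            a = np.concatenate([a, a2[ok]])
            b = np.concatenate([b, b2[ok]])
        return a[:m], b[:m]

    rows = []
    ca, cb = sample_pairs(config.n_close_pairs, True)
    snp = rng.poisson(config.close_snp_mean, size=config.n_close_pairs)
    bad = snp >= 500
    while bad.any():
        snp[bad] = rng.poisson(config.close_snp_mean, size=int(bad.sum()))
        bad = snp >= 500
    tip = rng.poisson(slope * snp)
    syn = rng.binomial(snp, config.syn_frac_close)
    rows.append(pd.DataFrame({
        "acc_a": panel["accession"].to_numpy()[ca],
        "acc_b": panel["accession"].to_numpy()[cb],
        "snp_diff": snp, "syn_snp_diff": syn, "tip_diff": tip,
        "pair_class": "close",
    }))

    da, db = sample_pairs(config.n_distant_pairs, config.n_groups == 1)
    snp = rng.poisson(config.distant_snp_mean, size=config.n_distant_pairs)
    bad = snp < 500
    while bad.any():
        snp[bad] = rng.poisson(config.distant_snp_mean, size=int(bad.sum()))
        bad = snp < 500
    tip = rng.poisson(config.retention_prob * config.syn_enrichment * slope * snp)
    syn = rng.binomial(snp, min(config.syn_frac_close * config.syn_enrichment, 0.95))
    rows.append(pd.DataFrame({
        "acc_a": panel["accession"].to_numpy()[da],
        "acc_b": panel["accession"].to_numpy()[db],
        "snp_diff": snp, "syn_snp_diff": syn, "tip_diff": tip,
        "pair_class": "all",
    }))
    return pd.concat(rows, ignore_index=True)


# -------------------------------------------------------------- expression

def simulate_expression(panel: pd.DataFrame, tips: TipGenotypeMatrix,
                        genes, config: CohortConfig, rng: np.random.Generator):
    """Per-gene log-normal expression, with carriers shifted at effectful genic TIPs."""
    acc = panel["accession"].to_numpy()
    gids = genes.genes.index.to_numpy()
    G, n = len(gids), len(acc)
    baseline = rng.lognormal(3.0, 0.6, size=G)
    expr = baseline[:, None] * rng.lognormal(0.0, config.expr_noise_sd, size=(G, n))

    gstart = genes.genes["start"].to_numpy()
    gend = genes.genes["end"].to_numpy()
    order = np.argsort(gstart)
    pos = tips.sites["pos"].to_numpy()
    idx = np.searchsorted(gstart[order], pos, side="right") - 1
    inside = (idx >= 0) & (pos < gend[order][np.clip(idx, 0, G - 1)])
    effects = []
    gindex = {g: i for i, g in enumerate(gids)}
    for s in np.flatnonzero(inside):
        if rng.random() >= config.expr_effect_fraction:
            continue
        gid = gids[order][idx[s]]
        site_id = tips.sites.index[s]
        carr = tips.states.iloc[s].to_numpy() == 1.0
        expr[gindex[gid], carr] *= config.expr_effect
        effects.append({"site_id": site_id, "gene_id": gid,
                        "effect": config.expr_effect})
    expression = pd.DataFrame(expr, index=pd.Index(gids, name="gene_id"), columns=acc)
    effects_df = pd.DataFrame(effects, columns=["site_id", "gene_id", "effect"])
    return expression, effects_df


# ------------------------------------------------------------------ cohort

def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; identical config + seed is bit-identical."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel, kinship = simulate_panel(config, rng)
    climate = simulate_climate(panel, config, rng)
    genes = simulate_genes(config, rng)
    tips, calls, truth_sites, windows, vr_truth = simulate_tip_data(
        panel, genes, climate, config, rng)
    pairs = simulate_divergence_pairs(panel, config, rng)
    expression, expr_effects = simulate_expression(panel, tips, genes, config, rng)
    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "config": dataclasses.asdict(config),
        "sites": truth_sites,
        "very_recent": vr_truth,
        "expression_effects": expr_effects,
        "elimination_true": 1.0 - config.retention_prob,
        "kappa_true": config.syn_enrichment,
    }
    return SyntheticCohort(panel=panel, kinship=kinship, tips=tips,
                           candidates=calls, pairs=pairs, climate=climate,
                           expression=expression, genes=genes, windows=windows,
                           truth=truth)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write every downstream input format to ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    cohort.panel.to_csv(p("panel.tsv"), sep="\t", index=False)
    pd.DataFrame(cohort.kinship,
                 index=cohort.panel["accession"],
                 columns=cohort.panel["accession"]).to_csv(p("kinship.tsv"), sep="\t")
    cohort.candidates.to_csv(p("calls.tsv"), sep="\t", index=False)
    cohort.tips.to_tsv(p("tips.tsv"))
    cohort.pairs.to_csv(p("pairs.tsv"), sep="\t", index=False)
    cohort.climate.to_csv(p("climate.csv"), index=False)
    cohort.expression.to_csv(p("expression.tsv"), sep="\t")
    cohort.genes.to_gff3(p("genes.gff3"))
    cohort.windows.to_csv(p("windows.tsv"), sep="\t", index=False)
    truth = dict(cohort.truth)
    for key in ("sites", "very_recent", "expression_effects"):
        truth[key] = truth[key].reset_index().to_dict(orient="list") \
            if truth[key].index.name else truth[key].to_dict(orient="list")
    with open(p("truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
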