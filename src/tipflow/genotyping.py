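"""Population-level TIP genotyping from per-sample candidate insertion calls.

Candidate transposable-element insertion/absence calls detected per resequenced
genome are merged into population-level sites, per-accession presence/absence/NA
states are called from read-coverage evidence, and a cascade of population
filters removes unreliable sites.  A separate filter implements the read-support
rules used for TE sequence-capture experiments.

Coordinates are 0-based half-open throughout; GFF3 I/O elsewhere converts to
1-based closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_DP = 3
DEFAULT_DROP_RATIO = 0.8
DEFAULT_MIN_INFORMATIVE = 100
#: (superfamily, variant class) pairs never genotyped: presence variants of
#: rolling-circle HELITRONs are not reliably detected by split-read evidence.
DEFAULT_BLACKLIST = (("HELITRON", "presence"),)

CALL_COLUMNS = [
    "sample", "chrom", "start", "end", "family", "superfamily", "var_class",
    "split_left", "split_right", "disc_left", "disc_right",
    "pos_cov", "neg_cov", "site_cov", "flank_cov", "library",
    "centromeric", "spans_donor", "fragmented_ref", "ancestral",
]

_EVIDENCE_COLS = ("pos_cov", "neg_cov", "site_cov", "flank_cov")


@dataclass
class MergedSites:
    """Population-level candidate sites with per-accession evidence arrays."""

    sites: pd.DataFrame          # indexed by site id
    accessions: list[str]
    evidence: dict[str, np.ndarray]   # each (n_sites, n_accessions)
    provenance: list[dict] = field(default_factory=list)


@dataclass
class TipGenotypeMatrix:
    """Sites x accessions presence(1)/absence(0)/NA genotype matrix.

    ``sites`` carries per-site metadata plus informative/carrier counts,
    frequency (carriers / informative genomes) and minor-allele frequency.
    ``evidence`` holds positive/negative coverage arrays aligned with
    ``states`` (needed by the heterozygous-like population filter).
    ``provenance`` logs every filter stage with its removal count.
    """

    sites: pd.DataFrame
    states: pd.DataFrame          # float: 1.0 present, 0.0 absent, NaN = NA
    evidence: dict[str, np.ndarray] | None = None
    provenance: list[dict] = field(default_factory=list)

    @property
    def accessions(self) -> list[str]:
        return list(self.states.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def recompute_stats(self) -> None:
        s = self.states.to_numpy()
        informative = np.sum(~np.isnan(s), axis=1)
        carriers = np.nansum(s, axis=1).astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(informative > 0, carriers / np.maximum(informative, 1), np.nan)
        self.sites = self.sites.assign(
            informative=informative,
            n_carriers=carriers,
            frequency=freq,
            maf=np.minimum(freq, 1.0 - freq),
        )

    def subset(self, keep: np.ndarray, stage: str) -> "TipGenotypeMatrix":
        keep = np.asarray(keep, dtype=bool)
        removed = int((~keep).sum())
        evidence = None
        if self.evidence is not None:
            evidence = {k: v[keep] for k, v in self.evidence.items()}
        out = TipGenotypeMatrix(
            sites=self.sites.loc[keep].copy(),
            states=self.states.loc[keep].copy(),
            evidence=evidence,
            provenance=self.provenance + [
                {"stage": stage, "removed": removed, "remaining": int(keep.sum())}
            ],
        )
        return out

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        meta = self.sites.copy()
        geno = self.states.copy()
        out = pd.concat([meta, geno], axis=1)
        out.index.name = "site_id"
        with open(path, "w") as fh:
            out.to_csv(fh, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, meta_cols=None) -> "TipGenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="site_id", na_values=["NA"])
        if meta_cols is None:
            known = [
                "chrom", "pos", "start", "end", "family", "superfamily",
                "var_class", "fragmented_ref", "ancestral", "informative",
                "n_carriers", "frequency", "maf",
            ]
            meta_cols = [c for c in known if c in df.columns]
        sites = df[meta_cols]
        states = df.drop(columns=meta_cols).astype(float)
        m = cls(sites=sites, states=states)
        m.recompute_stats()
        return m

    def write_provenance(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tremoved\tremaining\n")
            for rec in self.provenance:
                fh.write(f"{rec['stage']}\t{rec['removed']}\t{rec['remaining']}\n")


def merge_candidate_sites(
    calls: pd.DataFrame,
    dp: int = DEFAULT_DP,
    evidence_agg: str = "max",
) -> MergedSites:
    """Merge per-sample candidate intervals into population-level sites.

    Intervals of the same chromosome, TE family and variant class that overlap
    are merged transitively into one site.  The representative position is the
    midpoint of the intersection of all member intervals; when the intersection
    is empty (chained overlaps) the midpoint of the union is used.  Per-accession
    read evidence is aggregated across member calls (``max`` by default, ``sum``
    optional).  A site is retained only if at least one sample reaches ``dp``
    supporting reads (the DP filter).
    """
    if evidence_agg not in ("max", "sum"):
        raise ValueError("evidence_agg must be 'max' or 'sum'")
    calls = calls.copy()
    unknown = calls["family"].isna() | (calls["family"].astype(str) == "")
    if unknown.any():
        warnings.warn(f"skipping {int(unknown.sum())} calls with unknown TE family")
        calls = calls.loc[~unknown]
    if calls.empty:
        empty = pd.DataFrame(
            columns=["chrom", "pos", "start", "end", "family", "superfamily",
                     "var_class", "fragmented_ref", "ancestral"]
        )
        return MergedSites(sites=empty, accessions=[], evidence={}, provenance=[])

    calls = calls.sort_values(
        ["chrom", "family", "var_class", "start", "end"], kind="mergesort"
    ).reset_index(drop=True)
    gkey = (
        calls["chrom"].astype(str) + "\x00" + calls["family"].astype(str)
        + "\x00" + calls["var_class"].astype(str)
    )
    gcodes = pd.factorize(gkey)[0]
    grp = pd.Series(gcodes)
    cummax_end = calls.groupby(grp)["end"].cummax()
    prev_end = cummax_end.groupby(grp).shift(1)
    new_cluster = prev_end.isna() | (calls["start"] >= prev_end)
    calls["_cluster"] = new_cluster.cumsum()

    agg = calls.groupby("_cluster").agg(
        chrom=("chrom", "first"),
        family=("family", "first"),
        superfamily=("superfamily", "first"),
        var_class=("var_class", "first"),
        start=("start", "min"),
        end=("end", "max"),
        max_start=("start", "max"),
        min_end=("end", "min"),
        fragmented_ref=("fragmented_ref", "any"),
        ancestral=("ancestral", "any"),
    )
    inter_ok = agg["max_start"] < agg["min_end"]
    pos = np.where(
        inter_ok,
        (agg["max_start"] + agg["min_end"]) // 2,
        (agg["start"] + agg["end"]) // 2,
    )
    agg["pos"] = pos.astype(int)
    agg = agg.drop(columns=["max_start", "min_end"])

    accessions = sorted(calls["sample"].unique())
    aggfunc = evidence_agg
    evidence = {}
    for col in _EVIDENCE_COLS:
        piv = calls.pivot_table(
            index="_cluster", columns="sample", values=col,
            aggfunc=aggfunc, fill_value=0,
        ).reindex(index=agg.index, columns=accessions, fill_value=0)
        evidence[col.replace("_cov", "")] = piv.to_numpy(dtype=float)

    # DP filter: at least one sample with enough supporting reads
    keep = evidence["pos"].max(axis=1) >= dp
    n_removed = int((~keep).sum())
    agg = agg.loc[keep]
    evidence = {k: v[np.asarray(keep)] for k, v in evidence.items()}

    order = np.lexsort((agg["pos"].to_numpy(), agg["chrom"].to_numpy()))
    agg = agg.iloc[order]
    evidence = {k: v[order] for k, v in evidence.items()}
    agg.index = [f"TIP{i:06d}" for i in range(len(agg))]
    agg.index.name = "site_id"
    cols = ["chrom", "pos", "start", "end", "family", "superfamily",
            "var_class", "fragmented_ref", "ancestral"]
    prov = [{"stage": "dp_filter", "removed": n_removed, "remaining": len(agg)}]
    return MergedSites(sites=agg[cols], accessions=accessions,
                       evidence=evidence, provenance=prov)


def call_site_states(
    pos_cov, neg_cov, site_cov, flank_cov,
    dp: int = DEFAULT_DP, drop_ratio: float = DEFAULT_DROP_RATIO,
):
    """Call present / absent / NA states from coverage evidence.

    present: >= dp reads support the variant AND reference coverage over the
    site drops below ``drop_ratio`` x flanking coverage (100 bp up/down).
    absent: >= dp reads support the reference state and the presence test
    fails.  Otherwise the genome is uninformative (NA, returned as NaN).
    """
    pos_cov = np.asarray(pos_cov, dtype=float)
    neg_cov = np.asarray(neg_cov, dtype=float)
    site_cov = np.asarray(site_cov, dtype=float)
    flank_cov = np.asarray(flank_cov, dtype=float)
    present = (pos_cov >= dp) & (site_cov < drop_ratio * flank_cov)
    absent = ~present & (neg_cov >= dp)
    states = np.full(pos_cov.shape, np.nan)
    states[present] = 1.0
    states[absent] = 0.0
    return states


def call_states(
    merged: MergedSites, dp: int = DEFAULT_DP, drop_ratio: float = DEFAULT_DROP_RATIO
) -> TipGenotypeMatrix:
    """Apply per-accession state calling to every merged site."""
    states = call_site_states(
        merged.evidence["pos"], merged.evidence["neg"],
        merged.evidence["site"], merged.evidence["flank"],
        dp=dp, drop_ratio=drop_ratio,
    )
    m = TipGenotypeMatrix(
        sites=merged.sites.copy(),
        states=pd.DataFrame(states, index=merged.sites.index, columns=merged.accessions),
        evidence={"pos": merged.evidence["pos"], "neg": merged.evidence["neg"]},
        provenance=list(merged.provenance),
    )
    m.recompute_stats()
    return m


def apply_population_filters(
    matrix: TipGenotypeMatrix,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    blacklist=DEFAULT_BLACKLIST,
) -> TipGenotypeMatrix:
    """Filter cascade on the population genotype matrix.

    In order, logging removal counts per stage:

    1. superfamily/class blacklist (HELITRON presence variants by default);
    2. sites with fewer than ``min_informative`` non-NA genomes;
    3. presence sites where no carrier has positive > negative coverage
       (heterozygous-like calls, implausible in a selfer outside the lab);
    4. absence sites flagged as fragmented reference TEs or ancestral
       (shared with the outgroup) — rearrangements, not recent mobilization.
    """
    m = matrix
    bl = {(sf, vc) for sf, vc in blacklist} if blacklist else set()
    if bl:
        bad = np.array([
            (sf, vc) in bl
            for sf, vc in zip(m.sites["superfamily"], m.sites["var_class"])
        ])
        m = m.subset(~bad, "superfamily_class_blacklist")

    m.recompute_stats()
    m = m.subset(m.sites["informative"].to_numpy() >= min_informative, "min_informative")

    if m.evidence is None:
        raise ValueError("population filters require per-accession coverage evidence")
    carriers = m.states.to_numpy() == 1.0
    pos_gt_neg = m.evidence["pos"] > m.evidence["neg"]
    any_good_carrier = np.any(carriers & pos_gt_neg, axis=1)
    is_presence = (m.sites["var_class"] == "presence").to_numpy()
    has_carrier = carriers.any(axis=1)
    het_like = is_presence & has_carrier & ~any_good_carrier
    m = m.subset(~het_like, "no_carrier_pos_gt_neg")

    is_absence = (m.sites["var_class"] == "absence").to_numpy()
    flagged = is_absence & (
        m.sites["fragmented_ref"].to_numpy(dtype=bool)
        | m.sites["ancestral"].to_numpy(dtype=bool)
    )
    m = m.subset(~flagged, "flagged_absence")
    m.recompute_stats()
    return m


def genotype(
    calls: pd.DataFrame,
    dp: int = DEFAULT_DP,
    drop_ratio: float = DEFAULT_DROP_RATIO,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    blacklist=DEFAULT_BLACKLIST,
    evidence_agg: str = "max",
) -> TipGenotypeMatrix:
    """Full pipeline: merge candidates, call states, apply population filters."""
    merged = merge_candidate_sites(calls, dp=dp, evidence_agg=evidence_agg)
    matrix = call_states(merged, dp=dp, drop_ratio=drop_ratio)
    return apply_population_filters(
        matrix, min_informative=min_informative, blacklist=blacklist
    )


def capture_filter(
    calls: pd.DataFrame,
    min_support: int = 2,
    max_support: int = 15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain sample-specific insertions from a TE sequence-capture experiment.

    A call is kept when split + discordant read support on EACH side lies in
    [min_support, max_support], the insertion does not span centromeric repeats
    or its donor TE, and the identical site is detected in exactly one library.
    Returns the retained calls and per-family, per-library counts.
    """
    calls = calls.copy()
    left = calls["split_left"] + calls["disc_left"]
    right = calls["split_right"] + calls["disc_right"]
    ok = (
        (left >= min_support) & (left <= max_support)
        & (right >= min_support) & (right <= max_support)
        & ~calls["centromeric"].astype(bool)
        & ~calls["spans_donor"].astype(bool)
    )
    kept = calls.loc[ok].copy()
    key = list(zip(kept["chrom"], kept["start"], kept["end"], kept["family"]))
    kept["_key"] = key
    nlib = kept.groupby("_key")["library"].transform("nunique")
    kept = kept.loc[nlib == 1].drop(columns="_key")
    counts = (
        kept.groupby(["family", "library"]).size().rename("n_insertions").reset_index()
    )
    return kept.reset_index(drop=True), counts
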