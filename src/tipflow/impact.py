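"""Gene-feature assignment of TIPs, recurrence nulls, and expression impact.

Each insertion point is assigned to exactly one category relative to the gene
annotation (exon > 5'UTR > 3'UTR > intron > promoter/near within 250 bp >
within 2 kb > intergenic), the expected number of genes hit by randomly
redistributed insertions is estimated by permutation, and carrier vs
non-carrier expression contrasts are computed with resampling nulls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PROXIMAL_BP = 250
NEAR_GENE_BP = 2000
KNOCKOUT_RATIO = 0.1
PSEUDOCOUNT = 0.5

CATEGORIES = ["exon", "utr5", "utr3", "intron", "promoter", "near",
              "within_2kb", "intergenic"]
GENIC_CATEGORIES = ("exon", "utr5", "utr3", "intron", "promoter", "near")

_GFF_KIND = {"exon": "exon", "utr5": "five_prime_UTR", "utr3": "three_prime_UTR",
             "intron": "intron"}
_KIND_CAT = {"exon": "exon", "five_prime_UTR": "utr5",
             "three_prime_UTR": "utr3", "intron": "intron"}
_PRECEDENCE = ["exon", "utr5", "utr3", "intron"]


@dataclass
class GeneAnnotation:
    """Toy gene annotation: non-overlapping genes with nested feature intervals."""

    genes: pd.DataFrame        # index gene_id: chrom,start,end,strand,pseudogene,essential,pnps
    features: pd.DataFrame     # gene_id, kind, start, end (0-based half-open)

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gid, g in self.genes.iterrows():
                attrs = (f"ID={gid};pseudogene={int(bool(g['pseudogene']))};"
                         f"essential={int(bool(g['essential']))};pnps={g['pnps']:.4f}")
                fh.write(f"{g['chrom']}\ttipflow\tgene\t{g['start'] + 1}\t{g['end']}"
                         f"\t.\t{g['strand']}\t.\t{attrs}\n")
                feats = self.features.loc[self.features["gene_id"] == gid]
                for j, f in feats.reset_index(drop=True).iterrows():
                    fh.write(f"{g['chrom']}\ttipflow\t{f['kind']}\t{f['start'] + 1}"
                             f"\t{f['end']}\t.\t{g['strand']}\t.\t"
                             f"ID={gid}.{f['kind']}.{j};Parent={gid}\n")

    @classmethod
    def from_gff3(cls, path) -> "GeneAnnotation":
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                                keep_order=True)
        genes, features = [], []
        for g in db.features_of_type("gene"):
            gid = g.id
            genes.append({
                "gene_id": gid, "chrom": g.seqid,
                "start": g.start - 1, "end": g.end, "strand": g.strand,
                "pseudogene": bool(int(g.attributes.get("pseudogene", ["0"])[0])),
                "essential": bool(int(g.attributes.get("essential", ["0"])[0])),
                "pnps": float(g.attributes.get("pnps", ["nan"])[0]),
            })
        for kind in ("exon", "intron", "five_prime_UTR", "three_prime_UTR"):
            for f in db.features_of_type(kind):
                parent = f.attributes.get("Parent", [None])[0]
                features.append({"gene_id": parent, "kind": kind,
                                 "start": f.start - 1, "end": f.end})
        gdf = pd.DataFrame(genes).set_index("gene_id")
        fdf = pd.DataFrame(features, columns=["gene_id", "kind", "start", "end"])
        return cls(genes=gdf, features=fdf)


def assign_tip_to_feature(pos: int, genes: GeneAnnotation,
                          chrom: str = "chr1",
                          genome_length: int | None = None) -> tuple[str, str | None]:
    """Category and associated gene for one insertion point.

    Precedence inside genes: exon > 5'UTR > 3'UTR > intron.  Outside genes:
    strand-aware promoter (<= 250 bp upstream of the TSS) or near (<= 250 bp
    downstream), then within 2 kb of the nearest gene, else intergenic.
    """
    if pos < 0 or (genome_length is not None and pos >= genome_length):
        raise ValueError(f"position {pos} is off-chromosome")
    g = genes.genes.loc[genes.genes["chrom"] == chrom]
    if g.empty:
        return "intergenic", None
    starts = g["start"].to_numpy()
    ends = g["end"].to_numpy()
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    gids = g.index.to_numpy()[order]
    i = np.searchsorted(starts, pos, side="right") - 1
    if i >= 0 and pos < ends[i]:
        gid = gids[i]
        feats = genes.features.loc[genes.features["gene_id"] == gid]
        inside = feats.loc[(feats["start"] <= pos) & (pos < feats["end"]), "kind"]
        cats = {_KIND_CAT[k] for k in inside}
        for cat in _PRECEDENCE:
            if cat in cats:
                return cat, gid
        return "intron", gid
    # nearest gene left (index i) and right (index i+1)
    cand = []
    if i >= 0:
        cand.append((pos - ends[i] + 1, gids[i], "right_of_gene"))
    if i + 1 < len(starts):
        cand.append((starts[i + 1] - pos, gids[i + 1], "left_of_gene"))
    dist, gid, side = min(cand)
    strand = genes.genes.loc[gid, "strand"]
    upstream = (side == "left_of_gene") == (strand == "+")
    if dist <= PROXIMAL_BP:
        return ("promoter" if upstream else "near"), gid
    if dist <= NEAR_GENE_BP:
        return "within_2kb", gid
    return "intergenic", None


def assign_features(sites: pd.DataFrame, genes: GeneAnnotation,
                    genome_length: int | None = None) -> pd.DataFrame:
    """Vector version of :func:`assign_tip_to_feature` over a site table."""
    cats, gids = [], []
    for sid, row in sites.iterrows():
        cat, gid = assign_tip_to_feature(int(row["pos"]), genes,
                                         chrom=row.get("chrom", "chr1"),
                                         genome_length=genome_length)
        cats.append(cat)
        gids.append(gid)
    return pd.DataFrame({"category": cats, "gene_id": gids}, index=sites.index)


def gene_hit_counts(assignments: pd.DataFrame) -> pd.Series:
    """TIPs within or near (<= 250 bp) each gene."""
    hit = assignments.loc[
        assignments["category"].isin(("exon", "utr5", "utr3", "intron",
                                      "promoter", "near"))
    ]
    return hit.groupby("gene_id").size().sort_values(ascending=False)


def recurrence_null(n_tips: int, genes: GeneAnnotation, genome_length: int,
                    replicates: int = 10, seed=None, multi_hit_min: int = 3):
    """Permutation null for genes hit by uniformly redistributed insertions.

    Per replicate, ``n_tips`` uniform positions are drawn and a gene counts as
    hit when an insertion lands inside it or within 250 bp.  Returns means and
    SDs of hit genes and of multi-hit (>= ``multi_hit_min``) genes.
    """
    span = (genes.genes["end"] - genes.genes["start"]).sum()
    if genome_length < span:
        raise ValueError("genome length smaller than total gene span")
    rng = np.random.default_rng(seed)
    starts = np.maximum(genes.genes["start"].to_numpy() - PROXIMAL_BP, 0)
    ends = np.minimum(genes.genes["end"].to_numpy() + PROXIMAL_BP, genome_length)
    hits = np.empty(replicates)
    multi = np.empty(replicates)
    for r in range(replicates):
        pos = np.sort(rng.integers(0, genome_length, size=n_tips))
        counts = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
        hits[r] = np.sum(counts >= 1)
        multi[r] = np.sum(counts >= multi_hit_min)
    return {
        "genes_hit_mean": float(hits.mean()),
        "genes_hit_sd": float(hits.std(ddof=1)) if replicates > 1 else float("nan"),
        "multi_hit_mean": float(multi.mean()),
        "multi_hit_sd": float(multi.std(ddof=1)) if replicates > 1 else float("nan"),
        "genes_hit": hits,
        "multi_hit": multi,
    }


def multi_hit_enrichment(obs_multi: int, obs_hit_total: int,
                         null_multi_mean: float, null_hit_mean: float):
    """Fisher exact test of observed vs expected multi-hit gene counts."""
    table = np.array([
        [obs_multi, obs_hit_total - obs_multi],
        [round(null_multi_mean), round(null_hit_mean) - round(null_multi_mean)],
    ])
    if np.any(table < 0) or np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("degenerate 2x2 table")
    a, b = table[0]
    c, d = table[1]
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    _, p = stats.fisher_exact(table)
    return float(odds), float(p)


@dataclass
class ExpressionImpact:
    site_id: str
    gene_id: str
    n_carriers: int
    n_noncarriers: int
    carrier_mean: float
    noncarrier_mean: float
    ratio: float
    log2_ratio: float
    knockout: bool


def expression_ratio(states_row, expr_row, site_id="", gene_id="",
                     eps: float = PSEUDOCOUNT,
                     ko_threshold: float = KNOCKOUT_RATIO) -> ExpressionImpact | None:
    """Carrier vs non-carrier mean expression of the assigned gene.

    NA-state accessions are excluded; a pseudocount on both means avoids
    division by zero; the knock-out flag marks ratios at or below the
    threshold.  Returns None when no carrier (or no non-carrier) has
    expression data — the impact is undefined, not fabricated.
    """
    s = np.asarray(states_row, dtype=float)
    e = np.asarray(expr_row, dtype=float)
    ok = ~np.isnan(s) & ~np.isnan(e)
    carr = ok & (s == 1.0)
    nonc = ok & (s == 0.0)
    if carr.sum() == 0 or nonc.sum() == 0:
        return None
    mc = float(e[carr].mean())
    mn = float(e[nonc].mean())
    ratio = (mc + eps) / (mn + eps)
    return ExpressionImpact(
        site_id=site_id, gene_id=gene_id,
        n_carriers=int(carr.sum()), n_noncarriers=int(nonc.sum()),
        carrier_mean=mc, noncarrier_mean=mn,
        ratio=ratio, log2_ratio=float(np.log2(ratio)),
        knockout=ratio <= ko_threshold,
    )


def expression_impacts(matrix, expression: pd.DataFrame,
                       assignments: pd.DataFrame,
                       eps: float = PSEUDOCOUNT,
                       ko_threshold: float = KNOCKOUT_RATIO) -> pd.DataFrame:
    """Expression impact for every TIP assigned to a gene with expression data."""
    common = [a for a in matrix.states.columns if a in expression.columns]
    rows = []
    for sid in matrix.states.index:
        gid = assignments.loc[sid, "gene_id"]
        if gid is None or gid not in expression.index:
            continue
        imp = expression_ratio(
            matrix.states.loc[sid, common].to_numpy(),
            expression.loc[gid, common].to_numpy(),
            site_id=sid, gene_id=gid, eps=eps, ko_threshold=ko_threshold,
        )
        if imp is None:
            continue
        rows.append({
            "site_id": sid, "gene_id": gid,
            "category": assignments.loc[sid, "category"],
            "n_carriers": imp.n_carriers,
            "carrier_mean": imp.carrier_mean, "noncarrier_mean": imp.noncarrier_mean,
            "ratio": imp.ratio, "log2_ratio": imp.log2_ratio,
            "knockout": imp.knockout,
        })
    return pd.DataFrame(rows).set_index("site_id") if rows else pd.DataFrame(
        columns=["gene_id", "category", "n_carriers", "carrier_mean",
                 "noncarrier_mean", "ratio", "log2_ratio", "knockout"])


def extreme_ratio_excess(impacts: pd.DataFrame, expression: pd.DataFrame,
                         n_resamples: int = 100, lower_q: float = 0.05,
                         upper_q: float = 0.95, seed=None,
                         eps: float = PSEUDOCOUNT) -> pd.DataFrame:
    """Excess of extreme carrier/non-carrier log-ratios per category vs null.

    The null redraws, per TIP, a pseudo-carrier set of the same size from
    accessions with expression data and recomputes the log-ratio.  Extremeness
    thresholds are the per-category quantiles of the pooled null; the excess is
    the observed extreme count minus the null mean, with the resampling SD.
    """
    if n_resamples <= 0:
        raise ValueError("n_resamples must be positive")
    rng = np.random.default_rng(seed)
    acc = expression.columns
    n = len(acc)
    tips = impacts.reset_index()
    null = np.empty((len(tips), n_resamples))
    for t, row in tips.iterrows():
        e = expression.loc[row["gene_id"]].to_numpy(dtype=float)
        k = int(row["n_carriers"])
        total = e.sum()
        for r in range(n_resamples):
            idx = rng.choice(n, size=k, replace=False)
            mc = e[idx].mean()
            mn = (total - e[idx].sum()) / (n - k)
            null[t, r] = np.log2((mc + eps) / (mn + eps))
    out = []
    for cat in sorted(tips["category"].unique()):
        m = (tips["category"] == cat).to_numpy()
        pool = null[m].ravel()
        lo, hi = np.quantile(pool, [lower_q, upper_q])
        obs = tips.loc[m, "log2_ratio"].to_numpy()
        null_lo = (null[m] < lo).sum(axis=0)
        null_hi = (null[m] > hi).sum(axis=0)
        for side, thr, obs_n, null_n in (
            ("negative", lo, int((obs < lo).sum()), null_lo),
            ("positive", hi, int((obs > hi).sum()), null_hi),
        ):
            out.append({
                "category": cat, "side": side, "threshold": float(thr),
                "observed": obs_n, "null_mean": float(null_n.mean()),
                "null_sd": float(null_n.std(ddof=1)),
                "excess": obs_n - float(null_n.mean()),
            })
    return pd.DataFrame(out)


def combined_gene_effect(gene_id: str, site_ids, matrix, expression: pd.DataFrame,
                         eps: float = PSEUDOCOUNT) -> dict:
    """Pooled effect of all TIPs at one gene: carriers of any allele vs carriers of none."""
    common = [a for a in matrix.states.columns if a in expression.columns]
    states = matrix.states.loc[site_ids, common].to_numpy()
    carrier = np.nansum(states == 1.0, axis=0) > 0
    informative = ~np.all(np.isnan(states), axis=0)
    nonc = informative & ~carrier
    if carrier.sum() == 0:
        raise ValueError(f"{gene_id}: no carriers with expression data")
    if nonc.sum() == 0:
        raise ValueError(f"{gene_id}: every accession carries an allele")
    e = expression.loc[gene_id, common].to_numpy(dtype=float)
    mc, mn = e[carrier].mean(), e[nonc].mean()
    log2_ratio = float(np.log2((mc + eps) / (mn + eps)))
    stat, p = stats.mannwhitneyu(e[carrier], e[nonc], alternative="two-sided")
    per_tip = []
    for i in range(states.shape[0]):
        c = states[i] == 1.0
        o = states[i] == 0.0
        if c.sum() and o.sum():
            per_tip.append(np.log2((e[c].mean() + eps) / (e[o].mean() + eps)))
    concordant = len(per_tip) > 0 and (all(v >= 0 for v in per_tip)
                                       or all(v <= 0 for v in per_tip))
    return {"gene_id": gene_id, "n_tips": len(site_ids),
            "n_carriers": int(carrier.sum()), "n_noncarriers": int(nonc.sum()),
            "log2_ratio": log2_ratio, "p": float(p), "concordant": concordant}


def combined_gene_effects(matrix, expression: pd.DataFrame,
                          assignments: pd.DataFrame) -> pd.DataFrame:
    """Combined effect per gene with >= 1 assigned TIP, BH-corrected across genes."""
    from statsmodels.stats.multitest import multipletests

    rows = []
    for gid, sub in assignments.loc[assignments["gene_id"].notna()].groupby("gene_id"):
        if gid not in expression.index:
            continue
        try:
            rows.append(combined_gene_effect(gid, list(sub.index), matrix, expression))
        except ValueError as err:
            warnings.warn(str(err))
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def correlate_hits_pnps(hit_counts, pnps) -> tuple[float, float]:
    """Spearman correlation between per-gene TIP counts and pN/pS."""
    x = np.asarray(hit_counts, dtype=float)
    y = np.asarray(pnps, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 genes")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("undefined correlation for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
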