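import numpy as np
import pandas as pd
import pytest

from tipflow.genotyping import CALL_COLUMNS
from tipflow.synth import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-accession cohort shared by read-only tests."""
    cfg = CohortConfig(
        n_accessions=60, n_background_sites=120, seed=11,
        base_rate=2.0, gxe_effects={"BIO04": 0.4},
    )
    return simulate_cohort(cfg)


def make_call(sample, start, end, *, chrom="chr1", family="ATCOPIA93",
              superfamily="COPIA", var_class="presence",
              split_left=2, split_right=2, disc_left=1, disc_right=1,
              pos_cov=5.0, neg_cov=0.0, site_cov=2.0, flank_cov=10.0,
              library=None, centromeric=False, spans_donor=False,
              fragmented_ref=False, ancestral=False):
    """One candidate-call record with innocuous defaults (clean present call)."""
    return {
        "sample": sample, "chrom": chrom, "start": start, "end": end,
        "family": family, "superfamily": superfamily, "var_class": var_class,
        "split_left": split_left, "split_right": split_right,
        "disc_left": disc_left, "disc_right": disc_right,
        "pos_cov": pos_cov, "neg_cov": neg_cov, "site_cov": site_cov,
        "flank_cov": flank_cov,
        "library": library if library is not None else f"lib_{sample}",
        "centromeric": centromeric, "spans_donor": spans_donor,
        "fragmented_ref": fragmented_ref, "ancestral": ancestral,
    }


def calls_frame(records):
    return pd.DataFrame(records, columns=CALL_COLUMNS)


def match_truth_sites(merged_sites: pd.DataFrame, truth_sites: pd.DataFrame,
                      tol: int = 60):
    """Map genotyped sites back to generating truth sites by position/family/class."""
    out = []
    for _, row in merged_sites.iterrows():
        cand = truth_sites[
            (truth_sites["family"] == row["family"])
            & (truth_sites["var_class"] == row["var_class"])
            & (np.abs(truth_sites["pos"] - row["pos"]) < tol)
        ]
        out.append(cand.index[0] if len(cand) else None)
    return out
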