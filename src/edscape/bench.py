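"""FDR benchmarks for the site caller.

Two evaluation protocols: genotype-based (a called site is true when
the matched DNA genotype is homozygous reference) and knockdown-based
(the ratio of A-to-I sites surviving in an enzyme-knockdown run to
those in the control run, stratified by repeat class).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["genotype_fdr", "knockdown_fdr"]

REPEAT_CLASSES = ("Alu", "repetitive_nonAlu", "nonrepetitive")


def genotype_fdr(sites: pd.DataFrame, genotypes: pd.DataFrame) -> dict:
    """Genotype-based FDR of a called-sites table, as a percentage.

    Sites with a matched genotype record are true when ``hom_ref``,
    false otherwise; sites without genotype coverage (or with a
    ``missing`` genotype) are excluded from the denominator and counted
    separately.
    """
    sites = sites.drop_duplicates(["chrom", "pos"])
    merged = sites[["chrom", "pos"]].merge(
        genotypes.drop_duplicates(["chrom", "pos"]), on=["chrom", "pos"], how="left"
    )
    covered = merged["genotype"].notna() & (merged["genotype"] != "missing")
    n_true = int((merged.loc[covered, "genotype"] == "hom_ref").sum())
    n_false = int(covered.sum()) - n_true
    total = n_true + n_false
    return {
        "fdr_percent": (100.0 * n_false / total) if total else float("nan"),
        "n_true": n_true,
        "n_false": n_false,
        "n_uncovered": int((~covered).sum()),
    }


def knockdown_fdr(
    control_sites: pd.DataFrame,
    knockdown_sites: pd.DataFrame,
    canonical: str = "A-to-I",
) -> dict:
    """Knockdown-based FDR per repeat class, as percentages.

    FDR(class) = 100 * #A-to-I sites called in the knockdown run /
    #A-to-I sites called in the control run; NA when the control count
    in a class is zero.  Both inputs must come from runs with identical
    parameters.
    """
    def pick(df):
        out = df[df["canonical_type"] == canonical].drop_duplicates(["chrom", "pos"])
        return out

    ctrl = pick(control_sites)
    kd = pick(knockdown_sites)
    per_class = {}
    for rc in REPEAT_CLASSES:
        if "repeat_class" in ctrl.columns:
            n_ctrl = int((ctrl["repeat_class"] == rc).sum())
            n_kd = int((kd["repeat_class"] == rc).sum()) if "repeat_class" in kd.columns else 0
        else:
            n_ctrl, n_kd = 0, 0
        per_class[rc] = {
            "fdr_percent": (100.0 * n_kd / n_ctrl) if n_ctrl else float("nan"),
            "n_control": n_ctrl,
            "n_knockdown": n_kd,
        }
    n_ctrl, n_kd = len(ctrl), len(kd)
    return {
        "overall": {
            "fdr_percent": (100.0 * n_kd / n_ctrl) if n_ctrl else float("nan"),
            "n_control": n_ctrl,
            "n_knockdown": n_kd,
        },
        "per_class": per_class,
    }
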