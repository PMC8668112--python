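"""Site annotation: transcript class, splice windows, TFBS, repeat class.

The splice-site label is a distance-to-exon-boundary rule: a site is a
splice site when it lies within ``splice_window_bp`` of any annotated
exon edge (default 300 bp).  This is a stand-in for score-based splice
annotation databases and is recorded as such in output metadata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._io import read_bed

__all__ = ["load_transcript_models", "annotate_sites"]

TRANSCRIPT_CLASSES = ("lncRNA_only", "mRNA_only", "overlap", "intergenic")


def load_transcript_models(gtf_path):
    """Parse a GTF into transcript and exon tables via gffutils.

    Transcript class is derived from the ``transcript_biotype``
    attribute (``lncRNA`` vs anything else = mRNA).  Raises
    ``ValueError`` when the GTF carries no exon features.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tx_rows, exon_rows = [], []
    for tx in db.features_of_type("transcript"):
        biotype = (tx.attributes.get("transcript_biotype") or ["protein_coding"])[0]
        tx_rows.append(
            {
                "tx_id": tx.attributes["transcript_id"][0],
                "chrom": tx.seqid,
                "start": tx.start,
                "end": tx.end,
                "strand": tx.strand,
                "tx_class": "lncRNA" if biotype == "lncRNA" else "mRNA",
            }
        )
    for ex in db.features_of_type("exon"):
        tx_id = ex.attributes["transcript_id"][0]
        exon_id = (ex.attributes.get("exon_id") or [f"{tx_id}.e?"])[0]
        exon_rows.append(
            {
                "exon_id": exon_id,
                "tx_id": tx_id,
                "chrom": ex.seqid,
                "start": ex.start,
                "end": ex.end,
            }
        )
    if not exon_rows:
        raise ValueError(f"GTF {gtf_path} contains no exon features")
    transcripts = pd.DataFrame(tx_rows)
    exons = pd.DataFrame(exon_rows).merge(
        transcripts[["tx_id", "tx_class"]], on="tx_id", how="left"
    )
    return transcripts, exons


def _covers(pos: np.ndarray, chroms: np.ndarray, ivl: pd.DataFrame, one_based: bool):
    """Boolean matrix-free overlap: for each site, any covering interval?

    ``ivl`` needs chrom/start/end columns; ``one_based`` selects GTF
    (inclusive) vs BED (half-open) conventions.
    """
    hit = np.zeros(len(pos), dtype=bool)
    for chrom, sub in ivl.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        p = pos[sel]
        s = sub["start"].values[:, None]
        e = sub["end"].values[:, None]
        if one_based:
            m = (p >= s) & (p <= e)
        else:
            m = (p > s) & (p <= e)
        hit[sel] = m.any(axis=0)
    return hit


def annotate_sites(
    sites: pd.DataFrame,
    gtf_path,
    repeats_bed=None,
    tfbs_bed=None,
    splice_window_bp: int = 300,
) -> pd.DataFrame:
    """Annotate sites with transcript class, splice/TFBS flags, repeat class.

    Adds columns ``transcript_class``, ``is_splice_site``, ``is_tfbs``,
    ``repeat_class`` and ``exon_ids`` (semicolon-joined host exons).
    Annotation is idempotent and independent of row order.
    """
    transcripts, exons = load_transcript_models(gtf_path)
    out = sites.copy()
    pos = out["pos"].values.astype(np.int64)
    chroms = out["chrom"].values.astype(str)

    lnc = _covers(pos, chroms, transcripts[transcripts["tx_class"] == "lncRNA"], True)
    mrna = _covers(pos, chroms, transcripts[transcripts["tx_class"] == "mRNA"], True)
    tclass = np.where(
        lnc & mrna, "overlap",
        np.where(lnc, "lncRNA_only", np.where(mrna, "mRNA_only", "intergenic")),
    )
    out["transcript_class"] = tclass

    # host exons
    exon_ids = [""] * len(out)
    for chrom, sub in exons.groupby("chrom"):
        sel = np.nonzero(chroms == chrom)[0]
        if sel.size == 0:
            continue
        starts = sub["start"].values
        ends = sub["end"].values
        ids = sub["exon_id"].values
        for i in sel:
            m = (pos[i] >= starts) & (pos[i] <= ends)
            if m.any():
                exon_ids[i] = ";".join(sorted(ids[m]))
    out["exon_ids"] = exon_ids

    # splice windows around every exon boundary
    w = int(splice_window_bp)
    is_splice = np.zeros(len(out), dtype=bool)
    for chrom, sub in exons.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        bounds = np.unique(np.concatenate([sub["start"].values, sub["end"].values]))
        p = pos[sel]
        idx = np.searchsorted(bounds, p)
        dist = np.full(p.shape, np.iinfo(np.int64).max)
        left_ok = idx > 0
        dist[left_ok] = np.minimum(dist[left_ok], p[left_ok] - bounds[idx[left_ok] - 1])
        right_ok = idx < len(bounds)
        dist[right_ok] = np.minimum(
            dist[right_ok], bounds[np.minimum(idx[right_ok], len(bounds) - 1)] - p[right_ok]
        )
        is_splice[sel] = dist < w
    out["is_splice_site"] = is_splice

    # TFBS overlap
    if tfbs_bed is not None:
        tf = tfbs_bed if isinstance(tfbs_bed, pd.DataFrame) else read_bed(tfbs_bed)
        out["is_tfbs"] = _covers(pos, chroms, tf, one_based=False)
    else:
        out["is_tfbs"] = False

    # repeat class; Alu takes precedence over other repeats
    repeat_class = np.full(len(out), "nonrepetitive", dtype=object)
    if repeats_bed is not None:
        rep = repeats_bed if isinstance(repeats_bed, pd.DataFrame) else read_bed(repeats_bed)
        is_alu = rep["name"].astype(str).str.startswith("Alu")
        other_hit = _covers(pos, chroms, rep[~is_alu], one_based=False)
        alu_hit = _covers(pos, chroms, rep[is_alu], one_based=False)
        repeat_class[other_hit] = "repetitive_nonAlu"
        repeat_class[alu_hit] = "Alu"
    out["repeat_class"] = repeat_class
    return out
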