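"""Window-based mapping of significant SNPs to genes and QTL intervals.

A feature is reported for a SNP when its body [start, end] intersects the
window [pos - w, pos + w] (boundary inclusive; default w = 200 kb, chosen
to span the typical linkage-disequilibrium range of a commercial dairy
population).  Distances are gene-body distances (0 when the SNP falls
inside the feature); the side is reported relative to the SNP position.

Feature tables are 1-based inclusive on input (GFF3 convention); BED input
(0-based half-open) is converted by the reader.  Internally everything is
1-based inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["map_features", "overlap_report", "read_bed", "read_gff3"]

FEATURE_COLUMNS = ["feature", "chrom", "start", "end", "kind", "source"]


def _normalize_features(features: pd.DataFrame) -> pd.DataFrame:
    f = features.copy()
    for col, default in (("kind", "gene"), ("source", "")):
        if col not in f.columns:
            f[col] = default
    missing = [c for c in ("feature", "chrom", "start", "end") if c not in f.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    if (f["start"] > f["end"]).any():
        raise ValueError("feature start > end")
    return f[FEATURE_COLUMNS]


def map_features(
    snps: pd.DataFrame,
    features: pd.DataFrame,
    window: int = 200_000,
) -> pd.DataFrame:
    """Features within ``window`` bp of each SNP.

    Parameters
    ----------
    snps : DataFrame with columns ``snp``, ``chrom``, ``pos``.
    features : DataFrame with ``feature``, ``chrom``, ``start``, ``end``
        (1-based inclusive) and optional ``kind``/``source``.

    Returns one row per (snp, feature) pair with the gene-body distance
    and the side of the feature relative to the SNP (``within`` when the
    SNP lies inside the feature, else ``upstream``/``downstream`` for
    features ending before / starting after the SNP position).  SNPs on
    chromosomes absent from the feature table are flagged in
    ``result.attrs["unmatched_chromosomes"]`` rather than failing.
    """
    feats = _normalize_features(features)
    rows = []
    known_chroms = set(feats["chrom"].astype(str))
    unmatched = []
    for _, s in snps.iterrows():
        chrom = str(s["chrom"])
        pos = float(s["pos"])
        if chrom not in known_chroms:
            unmatched.append(s["snp"])
            continue
        sub = feats[feats["chrom"].astype(str) == chrom]
        hit = sub[(sub["start"] <= pos + window) & (sub["end"] >= pos - window)]
        for _, g in hit.iterrows():
            if g["start"] <= pos <= g["end"]:
                dist, side = 0, "within"
            elif g["end"] < pos:
                dist, side = int(pos - g["end"]), "upstream"
            else:
                dist, side = int(g["start"] - pos), "downstream"
            rows.append(
                {
                    "snp": s["snp"],
                    "chrom": chrom,
                    "pos": int(pos),
                    "feature": g["feature"],
                    "kind": g["kind"],
                    "start": int(g["start"]),
                    "end": int(g["end"]),
                    "distance": dist,
                    "side": side,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "snp",
            "chrom",
            "pos",
            "feature",
            "kind",
            "start",
            "end",
            "distance",
            "side",
        ],
    )
    out = out.sort_values(["snp", "chrom", "start"], kind="stable").reset_index(
        drop=True
    )
    out.attrs["unmatched_chromosomes"] = unmatched
    return out


def overlap_report(mapped_a: pd.DataFrame, mapped_b: pd.DataFrame) -> dict:
    """Shared/unique feature counts between two mapped sets (Venn input)."""
    set_a = set(mapped_a["feature"]) if len(mapped_a) else set()
    set_b = set(mapped_b["feature"]) if len(mapped_b) else set()
    shared = set_a & set_b
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_shared": len(shared),
        "n_only_a": len(set_a - set_b),
        "n_only_b": len(set_b - set_a),
        "shared": sorted(shared),
        "only_a": sorted(set_a - set_b),
        "only_b": sorted(set_b - set_a),
    }


def read_bed(path, kind: str = "qtl", source: str = "bed") -> pd.DataFrame:
    """Read a BED file (0-based half-open) into the 1-based feature table."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "feature"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(int)
    df["kind"] = kind
    df["source"] = source
    return df[FEATURE_COLUMNS]


def _gff3_attr(attrs: str, keys=("Name", "gene_name", "ID")) -> str:
    fields = dict(
        kv.split("=", 1) for kv in str(attrs).split(";") if "=" in kv
    )
    for k in keys:
        if k in fields:
            return fields[k]
    return str(attrs)


def read_gff3(path, feature_types=("gene",), source: str = "gff3") -> pd.DataFrame:
    """Read gene features from a GFF3 file (1-based inclusive, kept as is)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=[
            "chrom",
            "src",
            "type",
            "start",
            "end",
            "score",
            "strand",
            "phase",
            "attributes",
        ],
        dtype={"chrom": str},
    )
    if feature_types:
        df = df[df["type"].isin(feature_types)]
    out = pd.DataFrame(
        {
            "feature": df["attributes"].map(_gff3_attr),
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "kind": "gene",
            "source": source,
        }
    )
    return out.reset_index(drop=True)
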