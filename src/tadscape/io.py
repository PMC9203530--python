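"""Plain-text interchange formats: BED, bedGraph, BEDPE, variant/block TSV,
expression TSV and a YAML run manifest.

All coordinates are 0-based half-open.  Readers and writers round-trip
bit-identically on canonicalized (sorted) frames; undefined track bins are
omitted from bedGraph rather than written as zero.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

BED_COLS = ["chrom", "start", "end"]
BEDPE_COLS = ["chrom", "startA", "endA", "startB", "endB"]


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = BED_COLS + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    names = BED_COLS + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str})
    return df


def write_bedgraph(track: pd.DataFrame, path) -> None:
    """Write (chrom, start, end, value); NaN-valued bins are omitted."""
    out = track.dropna(subset=["value"])
    out[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )


def write_bedpe(loops: pd.DataFrame, path) -> None:
    """BEDPE with both anchors on one chromosome."""
    out = pd.DataFrame(
        {
            "chrom1": loops["chrom"],
            "start1": loops["startA"],
            "end1": loops["endA"],
            "chrom2": loops["chrom"],
            "start2": loops["startB"],
            "end2": loops["endB"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path) -> pd.DataFrame:
    raw = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        dtype={"chrom1": str, "chrom2": str},
        usecols=range(6),
    )
    if (raw["chrom1"] != raw["chrom2"]).any():
        raise ValueError(f"{path}: inter-chromosomal loop records not supported")
    return pd.DataFrame(
        {
            "chrom": raw["chrom1"],
            "startA": raw["start1"],
            "endA": raw["end1"],
            "startB": raw["start2"],
            "endB": raw["end2"],
        }
    )


def write_variants(snps: pd.DataFrame, deletions: pd.DataFrame, path) -> None:
    """Variant TSV: chrom, pos0, end0, type in {SNP, DEL}."""
    rows = [
        pd.DataFrame(
            {"chrom": snps["chrom"], "start": snps["pos"], "end": snps["pos"] + 1, "type": "SNP"}
        ),
        pd.DataFrame(
            {"chrom": deletions["chrom"], "start": deletions["start"], "end": deletions["end"], "type": "DEL"}
        ),
    ]
    out = pd.concat(rows, ignore_index=True).sort_values(
        ["chrom", "start", "end", "type"], kind="stable"
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_variants(path) -> dict:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "type"],
        dtype={"chrom": str},
    )
    snps = df[df["type"] == "SNP"][["chrom", "start"]].rename(columns={"start": "pos"})
    dels = df[df["type"] == "DEL"][["chrom", "start", "end"]]
    return {"snps": snps.reset_index(drop=True), "deletions": dels.reset_index(drop=True)}


BLOCK_COLS = ["qname", "qstart", "qend", "strand", "tname", "tstart", "tend", "alignable_bp"]


def write_blocks(blocks: pd.DataFrame, path) -> None:
    blocks[BLOCK_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_blocks(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=BLOCK_COLS,
        dtype={"qname": str, "tname": str, "strand": str},
    )


def write_expression(counts: pd.DataFrame, path) -> None:
    """Expression TSV: bin_id, chrom, start, end, then one column per sample."""
    ids = counts.index.to_series().astype(str)
    coords = ids.str.extract(r"(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)")
    out = pd.DataFrame({"bin_id": ids.to_numpy()})
    out["chrom"] = coords["chrom"].to_numpy()
    out["start"] = coords["start"].astype(int).to_numpy()
    out["end"] = coords["end"].astype(int).to_numpy()
    for c in counts.columns:
        out[c] = counts[c].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.set_index("bin_id")
    return df.drop(columns=["chrom", "start", "end"])


def write_manifest(entries: dict, seed: int, path) -> None:
    """YAML manifest listing emitted files and the generating seed."""
    doc = {"seed": int(seed), "files": {k: str(v) for k, v in entries.items()}}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
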