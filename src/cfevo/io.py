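"""Readers and writers for the plain-text formats the pipeline exchanges:
BED bin grids and gene lists, TSV bin counts and position lists, IGV-dialect
SEG segment files, VCF variant tables, and JSON clone-model/truth sidecars.

Coordinates are 0-based half-open internally and in BED; SEG output is
converted to 1-based inclusive (the IGV dialect)."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .cnv import BinCounts, BinGrid, SegmentProfile
from .errors import InvalidArgument

__all__ = [
    "read_bed",
    "read_bin_counts_tsv",
    "write_bin_counts_tsv",
    "read_positions_tsv",
    "write_seg",
    "read_seg",
    "write_vcf",
    "write_clone_model_json",
    "write_truth_json",
]


def read_bed(path) -> pd.DataFrame:
    """BED3/BED4+ into a DataFrame with chrom/start/end[/name]."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InvalidArgument(f"malformed BED line {ln}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InvalidArgument(f"malformed BED line {ln}: {line!r}") from exc
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) > 3:
                row["name"] = parts[3]
            rows.append(row)
    return pd.DataFrame(rows)


def read_bin_counts_tsv(path) -> BinCounts:
    """TSV with chrom/start/end/count columns into a BinCounts."""
    df = pd.read_csv(path, sep="\t")
    grid = BinGrid.from_dataframe(df)
    return BinCounts(grid=grid, raw=df["count"].to_numpy(np.int64))


def write_bin_counts_tsv(counts: BinCounts, path):
    df = counts.grid.to_dataframe()
    df["count"] = counts.raw
    if counts.ratio is not None:
        df["ratio"] = counts.ratio
        df["log2ratio"] = counts.log2ratio
    df.to_csv(path, sep="\t", index=False)


def read_positions_tsv(path) -> pd.DataFrame:
    """Aligned-read start positions: TSV with chrom/pos columns."""
    return pd.read_csv(path, sep="\t")[["chrom", "pos"]]


def write_seg(profile: SegmentProfile, sample: str, path):
    """IGV SEG file: 1-based inclusive coordinates, segment mean per row."""
    seg = profile.segments
    df = pd.DataFrame(
        {
            "ID": sample,
            "chrom": seg["chrom"],
            "loc.start": seg["start_bp"] + 1,
            "loc.end": seg["end_bp"],
            "num.mark": seg["n_bins"],
            "seg.mean": seg["mean_ratio"],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    """SEG file back to 0-based half-open segment rows."""
    df = pd.read_csv(path, sep="\t")
    return pd.DataFrame(
        {
            "sample": df["ID"],
            "chrom": df["chrom"],
            "start_bp": df["loc.start"] - 1,
            "end_bp": df["loc.end"],
            "n_bins": df["num.mark"],
            "mean_ratio": df["seg.mean"],
        }
    )


def write_vcf(
    table: pd.DataFrame,
    path,
    timepoint: int = 1,
    plasma_sample: str = "PLASMA",
    normal_sample: str = "NORMAL",
    contigs: dict | None = None,
):
    """Write a simulated mutation table as a VCF with plasma/normal AD fields.

    ``table`` is the output of the variant simulator (or any frame with
    chrom/pos/ref/alt, alt_t{n}/depth_t{n}, normal_alt/normal_depth, and
    optional gene/sift/polyphen/exonic_class columns).
    """
    alt_col, dep_col = f"alt_t{timepoint}", f"depth_t{timepoint}"
    extra_filters = set()
    if "filter" in table.columns:
        for val in table["filter"]:
            extra_filters.update(str(val).split(";"))
    extra_filters -= {"PASS", "germline_risk", "."}
    if contigs is None:
        contigs = {
            c: int(sub["pos"].max()) + 1000 for c, sub in table.groupby("chrom")
        }
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=PASS,Description="High confidence somatic">',
        '##FILTER=<ID=germline_risk,Description="Borderline somatic">',
        *[f'##FILTER=<ID={f},Description="Caller filter">' for f in sorted(extra_filters)],
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=SIFT,Number=1,Type=Float,Description="SIFT score">',
        '##INFO=<ID=POLYPHEN,Number=1,Type=Float,Description="PolyPhen score">',
        '##INFO=<ID=EXONIC_CLASS,Number=1,Type=String,Description="Exonic class">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
    ]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{plasma_sample}\t{normal_sample}"
    )
    table = table.sort_values(["chrom", "pos"])
    for row in table.itertuples():
        info = []
        for key, attr in (
            ("GENE", "gene"),
            ("SIFT", "sift"),
            ("POLYPHEN", "polyphen"),
            ("EXONIC_CLASS", "exonic_class"),
        ):
            val = getattr(row, attr, None)
            if val is not None and not (isinstance(val, float) and np.isnan(val)):
                info.append(f"{key}={val}")
        filt = getattr(row, "filter", "PASS")
        p_alt = int(getattr(row, alt_col))
        p_dep = int(getattr(row, dep_col))
        n_alt = int(row.normal_alt)
        n_dep = int(row.normal_depth)
        lines.append(
            "\t".join(
                [
                    str(row.chrom),
                    str(int(row.pos)),
                    ".",
                    row.ref,
                    row.alt,
                    ".",
                    filt,
                    ";".join(info) or ".",
                    "AD:DP",
                    f"{p_dep - p_alt},{p_alt}:{p_dep}",
                    f"{n_dep - n_alt},{n_alt}:{n_dep}",
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_clone_model_json(model, path):
    """Clone model (tree, prevalences, assignments) as JSON."""
    payload = {
        "k": model.k,
        "parent": list(model.parent),
        "clone_prevalence": model.clone_prevalence.tolist(),
        "fit_error": model.fit_error,
        "assignment": None if model.assignment is None else model.assignment.tolist(),
        "keys": None if model.keys is None else [list(k) for k in model.keys],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_truth_json(tree, path):
    """Simulator ground truth sidecar."""
    payload = {
        "clones": [
            {
                "clone_id": c.clone_id,
                "parent_id": c.parent_id,
                "cna_payload": [list(x) for x in c.cna_payload],
                "snv_payload": [list(x) for x in c.snv_payload],
                "prevalence": np.asarray(c.prevalence).tolist(),
            }
            for c in tree.clones
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
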