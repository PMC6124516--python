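"""Readers and writers for the pipeline's plain-text formats.

Dialects:

- count matrix: TSV, genes x samples, first column ``gene_id``;
- sample sheet: CSV with ``sample_id``, ``sex``, ``tissue``;
- gene annotation: BED-like TSV with ``gene_id``, ``chromosome``,
  ``tss`` (0-based), ``strand``, ``known_xci_status``;
- CpG calls: Bismark-coverage-style TSV, one file per sample, columns
  chromosome, start (1-based), end, methylation %, count methylated,
  count unmethylated.  Positions are converted to 0-based internally and
  back on writing.  Calls on the two strands of a CpG dinucleotide are
  distinct positions unless the input pre-merges them.
- metabolites: long CSV with ``subject_id``, ``visit_wkGA``,
  ``run_day``, ``metabolite_id``, ``raw_ion_count`` (empty = missing),
  ``fetal_sex``;
- promoter windows: 4-column BED (0-based half-open);
- ground truth and stage reports: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CountMatrix

__all__ = [
    "read_count_matrix", "write_count_matrix",
    "read_sample_sheet", "write_sample_sheet",
    "read_annotation", "write_annotation",
    "read_cpg_coverage", "write_cpg_coverage",
    "read_metabolite_table", "write_metabolite_table",
    "write_promoter_bed", "write_json", "read_json",
]

_XCI_STATUSES = {"escaped", "inactive", "variable", "unknown"}


def read_count_matrix(counts_path: str | Path,
                      sample_sheet_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in count matrix: {dup}")
    bad = ~np.isfinite(counts.to_numpy(dtype=float))
    if bad.any():
        r = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric count at row {r[0] + 2} of {counts_path}")
    sheet = read_sample_sheet(sample_sheet_path)
    sheet = sheet.loc[sheet.index.intersection(counts.columns)]
    tissues = sheet["tissue"].unique()
    tissue = tissues[0] if len(tissues) == 1 else "mixed"
    return CountMatrix(counts=counts.astype(int), sex=sheet["sex"],
                       tissue=tissue)


def write_count_matrix(cm: CountMatrix, counts_path: str | Path,
                       sample_sheet_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    sheet = pd.DataFrame({"sample_id": cm.sex.index, "sex": cm.sex.to_numpy(),
                          "tissue": cm.tissue})
    sheet.to_csv(sample_sheet_path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    for col in ("sample_id", "sex"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet lacks column '{col}'")
    if "tissue" not in sheet.columns:
        sheet["tissue"] = "unknown"
    bad = ~sheet["sex"].isin(["F", "M"])
    if bad.any():
        line = int(sheet.index[bad][0]) + 2
        raise ValueError(f"invalid sex label at line {line} of {path}")
    return sheet.set_index("sample_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chromosome", "tss", "strand"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation lacks column(s): {missing}")
    if "known_xci_status" not in ann.columns:
        ann["known_xci_status"] = "unknown"
    if ann["gene_id"].duplicated().any():
        dup = ann.loc[ann["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id in annotation: {dup}")
    neg = ann["tss"] < 0
    if neg.any():
        line = int(ann.index[neg][0]) + 2
        raise ValueError(f"negative TSS at line {line} of {path}")
    badstrand = ~ann["strand"].isin(["+", "-"])
    if badstrand.any():
        line = int(ann.index[badstrand][0]) + 2
        raise ValueError(f"invalid strand at line {line} of {path}")
    badstatus = ~ann["known_xci_status"].isin(_XCI_STATUSES)
    if badstatus.any():
        line = int(ann.index[badstatus][0]) + 2
        raise ValueError(f"invalid known_xci_status at line {line} of {path}")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene_id", "chromosome", "tss", "strand", "known_xci_status"]
    ann.reset_index().reindex(columns=cols).to_csv(path, sep="\t", index=False)


def read_cpg_coverage(path: str | Path, sample_id: str,
                      sex: str | None = None) -> pd.DataFrame:
    """Read one Bismark-coverage-style file into long CpG records.

    Input positions are 1-based; internal positions are 0-based.
    Malformed rows are reported with their line number.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chromosome", "start", "end", "meth_pct",
                            "count_methylated", "count_unmethylated"])
    for col in ("count_methylated", "count_unmethylated"):
        neg = df[col] < 0
        if neg.any():
            line = int(df.index[neg][0]) + 1
            raise ValueError(f"negative {col} at line {line} of {path}")
    total = df["count_methylated"] + df["count_unmethylated"]
    with np.errstate(invalid="ignore", divide="ignore"):
        implied = np.where(total > 0, 100.0 * df["count_methylated"] / total,
                           0.0)
    off = np.abs(implied - df["meth_pct"].to_numpy(dtype=float)) > 1.0
    if off.any():
        line = int(df.index[off][0]) + 1
        raise ValueError(
            f"methylation % inconsistent with counts at line {line} of {path}")
    out = pd.DataFrame({
        "chromosome": df["chromosome"],
        "position": df["start"].astype(int) - 1,
        "methylated_reads": df["count_methylated"].astype(int),
        "total_reads": total.astype(int),
        "sample_id": sample_id,
    })
    if sex is not None:
        out["sex"] = sex
    return out


def write_cpg_coverage(records: pd.DataFrame, path: str | Path) -> None:
    """Write long CpG records for one sample in Bismark-coverage dialect."""
    samples = records["sample_id"].unique()
    if len(samples) > 1:
        raise ValueError("one coverage file holds exactly one sample")
    meth = records["methylated_reads"].astype(int)
    unmeth = (records["total_reads"] - records["methylated_reads"]).astype(int)
    total = records["total_reads"].replace(0, np.nan)
    pct = (100.0 * records["methylated_reads"] / total).fillna(0.0)
    out = pd.DataFrame({
        "chromosome": records["chromosome"],
        "start": records["position"].astype(int) + 1,
        "end": records["position"].astype(int) + 1,
        "meth_pct": pct.round(6),
        "count_methylated": meth,
        "count_unmethylated": unmeth,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_metabolite_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["subject_id", "visit_wkGA", "run_day", "metabolite_id",
                "raw_ion_count", "fetal_sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"metabolite table lacks column(s): {missing}")
    neg = df["raw_ion_count"] < 0
    if neg.any():
        line = int(df.index[neg][0]) + 2
        raise ValueError(f"negative ion count at line {line} of {path}")
    dup = df.duplicated(subset=["subject_id", "visit_wkGA", "metabolite_id"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(
            f"duplicate (subject, visit, metabolite) record at line {line}")
    return df


def write_metabolite_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["subject_id", "visit_wkGA", "run_day", "metabolite_id",
            "raw_ion_count", "fetal_sex"]
    df.reindex(columns=cols).to_csv(path, index=False, float_format="%.10g")


def write_promoter_bed(windows: pd.DataFrame, path: str | Path) -> None:
    windows[["chromosome", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
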