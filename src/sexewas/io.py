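"""TSV readers/writers for the pipeline's on-disk contracts.

All tables are UTF-8 TSV with '.' decimal; matrices carry probe ids in the
first column. Probe coordinates are 1-based inclusive (manifest
convention); BED-style region tables use 0-based half-open coordinates,
converted at this boundary.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_study(study, outdir) -> list:
    """Write a SimulatedStudy to a directory; returns the file list."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for c in study.cohorts:
        d = out / c.name
        d.mkdir(exist_ok=True)
        write_matrix(c.beta, d / "beta.tsv.gz")
        write_matrix(c.detp, d / "detP.tsv.gz")
        write_table(c.samples, d / "samples.tsv")
        files += [str(d / "beta.tsv.gz"), str(d / "detP.tsv.gz"), str(d / "samples.tsv")]
    write_table(study.probes, out / "probes.tsv")
    write_table(study.truth, out / "truth.tsv")
    write_table(study.cets_reference, out / "cets_reference.tsv")
    pd.Series(study.smoking_probes, name="probe_id").to_csv(
        out / "smoking_probes.tsv", sep="\t", index=False)
    files += [str(out / f) for f in
              ("probes.tsv", "truth.tsv", "cets_reference.tsv", "smoking_probes.tsv")]
    return files


def regions_to_bed(regions: list) -> pd.DataFrame:
    """Region list -> BED-like table (0-based half-open, probes comma-joined)."""
    rows = []
    for r in regions:
        start = r.get("start")
        end = r.get("end")
        rows.append({
            "chr": r["chr"],
            "start": (start - 1) if start is not None else -1,
            "end": end if end is not None else -1,
            "probe_ids": ",".join(r["probes"]),
        })
    return pd.DataFrame(rows)


def bed_to_regions(bed: pd.DataFrame) -> list:
    out = []
    for _, row in bed.iterrows():
        out.append({"chr": row["chr"], "start": int(row["start"]) + 1,
                    "end": int(row["end"]), "probes": row["probe_ids"].split(",")})
    return out
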