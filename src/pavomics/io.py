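"""CSV/TSV readers and writers mirroring the deposited file shapes.

Expression matrices are written one file per tissue (``T_<tissue>.csv``,
rows = genes, columns = inbreds, FPKM), presence/absence call matrices as
1/0 with empty cells for no-calls (``ePAV_<scope>.csv``), the SNP-array
data as allele letters with empty cells for missing calls plus a
population-map sidecar, annotation as a tab-separated table with 1-based
inclusive coordinates, and phenotypes as one row per inbred.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pav_calling import ABSENT, NOCALL, NODATA, PACallMatrix, PRESENT
from .synthetic import (
    CALL_A,
    CALL_B,
    CALL_HET,
    CALL_MISSING,
    ExpressionTensor,
    PopulationGenotypes,
)

__all__ = [
    "write_expression",
    "read_expression",
    "write_pa_calls",
    "read_pa_calls",
    "write_annotation",
    "read_annotation",
    "write_populations",
    "read_populations",
    "write_phenotypes",
    "read_phenotypes",
]

_GENO_TO_STR = {CALL_A: "A", CALL_HET: "H", CALL_B: "B", CALL_MISSING: ""}
_STR_TO_GENO = {"A": CALL_A, "H": CALL_HET, "B": CALL_B, "": CALL_MISSING}


def write_expression(expr: ExpressionTensor, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tissue in expr.tissues:
        p = outdir / f"T_{tissue}.csv"
        expr.fpkm[tissue].to_csv(p)
        paths.append(p)
    return paths


def read_expression(outdir: str | Path) -> dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    out = {}
    for p in sorted(outdir.glob("T_*.csv")):
        out[p.stem[2:]] = pd.read_csv(p, index_col=0)
    if not out:
        raise FileNotFoundError(f"no T_<tissue>.csv files in {outdir}")
    return out


def write_pa_calls(calls: PACallMatrix, path: str | Path) -> Path:
    path = Path(path)
    mapped = calls.calls.replace({PRESENT: "1", ABSENT: "0", NOCALL: "", NODATA: ""})
    mapped.to_csv(path)
    return path


def read_pa_calls(path: str | Path, scope: str = "consensus") -> PACallMatrix:
    df = pd.read_csv(path, index_col=0)
    arr = df.to_numpy(dtype=float)
    coded = np.full(arr.shape, NOCALL, dtype=np.int8)
    coded[arr == 1] = PRESENT
    coded[arr == 0] = ABSENT
    return PACallMatrix(pd.DataFrame(coded, index=df.index, columns=df.columns), scope)


def write_annotation(anno: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["gene_id", "chrom", "start", "end", "strand", "cds_start", "cds_end"]
    anno[cols].to_csv(path, sep="\t", index=False)
    return path


def read_annotation(path: str | Path) -> pd.DataFrame:
    anno = pd.read_csv(path, sep="\t")
    anno["length"] = anno["end"] - anno["start"] + 1
    return anno.set_index("gene_id", drop=False)


def write_populations(
    pops: list[PopulationGenotypes], outdir: str | Path
) -> tuple[Path, Path]:
    """SNParray.csv (SNP x progeny allele letters, empty = missing) plus a
    popmap.csv sidecar mapping populations to parents and progeny columns."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mats, rows = [], []
    for pop in pops:
        mats.append(pop.genotypes.replace(_GENO_TO_STR))
        rows.append(
            (pop.population_id, pop.parent_a, pop.parent_b, ";".join(pop.genotypes.columns))
        )
    arr_path = outdir / "SNParray.csv"
    pd.concat(mats, axis=1).to_csv(arr_path)
    map_path = outdir / "popmap.csv"
    pd.DataFrame(rows, columns=["population_id", "parent_a", "parent_b", "progeny"]).to_csv(
        map_path, index=False
    )
    return arr_path, map_path


def read_populations(
    array_path: str | Path, popmap_path: str | Path
) -> list[PopulationGenotypes]:
    arr = pd.read_csv(array_path, index_col=0, keep_default_na=False, dtype=str)
    popmap = pd.read_csv(popmap_path)
    pops = []
    for rec in popmap.itertuples():
        cols = rec.progeny.split(";")
        sub = arr[cols].map(_STR_TO_GENO.get).astype(np.int8)
        pops.append(PopulationGenotypes(rec.population_id, rec.parent_a, rec.parent_b, sub))
    return pops


def write_phenotypes(y: pd.Series | pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df = y.to_frame() if isinstance(y, pd.Series) else y
    df.rename_axis("inbred").to_csv(path)
    return path


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
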