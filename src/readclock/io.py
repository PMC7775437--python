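"""Readers and writers for the package's on-disk formats.

Convention: percent on disk, fraction in memory — DNAm levels in CSV
files are percentages to match how the field reports them, and are
converted to [0,1] fractions at the boundary. Floats are serialised
with 17 significant digits so every writer/reader pair is an exact
inverse on its domain. See docs/FORMATS.md for column layouts.
"""

from __future__ import annotations

import gzip
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .amplicon import AmpliconSpec, ReadPatternTable
from .clocks import ClockModel, MethylationMatrix
from .single_read import AGE_GRID, ReadAgeDistribution, SingleReadModel

__all__ = [
    "read_beta_csv",
    "write_beta_csv",
    "read_model_json",
    "write_model_json",
    "read_pattern_tsv",
    "write_pattern_tsv",
    "read_distribution_csv",
    "write_distribution_csv",
    "read_panel",
    "write_panel",
    "read_fastq_seqs",
]

MODEL_SCHEMA = "readclock-model/1"
_FLOAT_FMT = "%.17g"


# ----------------------------------------------------------------- beta CSV

def read_beta_csv(path: str | Path) -> MethylationMatrix:
    """Load a samples x CpGs DNAm table (percent) with age metadata.

    Requires columns ``sample_id`` and ``age_weeks``; ``strain`` is
    optional; every other column is a CpG id. Values outside [0, 100]
    or non-numeric become missing with a warning.
    """
    df = pd.read_csv(path)
    required = [c for c in ("sample_id", "age_weeks") if c not in df.columns]
    if required:
        raise ValueError(f"beta CSV missing required columns: {required}")
    df = df.set_index("sample_id")
    ages = pd.to_numeric(df.pop("age_weeks"), errors="coerce")
    strain = df.pop("strain") if "strain" in df.columns else None
    betas = df.apply(pd.to_numeric, errors="coerce")
    n_coerced = int(df.notna().sum().sum() - betas.notna().sum().sum())
    vals = betas.to_numpy(dtype=float)
    out_of_range = (vals < 0) | (vals > 100)
    n_bad = int(np.nansum(out_of_range))
    if n_coerced or n_bad:
        warnings.warn(
            f"{path}: {n_coerced} malformed and {n_bad} out-of-range DNAm cells set to missing",
            stacklevel=2,
        )
    vals = np.where(out_of_range, np.nan, vals)
    betas = pd.DataFrame(vals / 100.0, index=betas.index, columns=betas.columns)
    return MethylationMatrix(betas, ages, strain)


def write_beta_csv(matrix: MethylationMatrix, path: str | Path) -> None:
    out = (matrix.betas * 100.0).copy()
    out.insert(0, "age_weeks", matrix.ages)
    if matrix.strain is not None:
        out.insert(1, "strain", matrix.strain)
    out.index.name = "sample_id"
    out.to_csv(path, float_format=_FLOAT_FMT)


# --------------------------------------------------------------- model JSON

def write_model_json(model: ClockModel | SingleReadModel, path: str | Path) -> None:
    """Serialise a clock or single-read model (one stable JSON dialect)."""
    if isinstance(model, SingleReadModel):
        payload = {
            "schema": MODEL_SCHEMA,
            "kind": "single-read",
            "amplicon": model.amplicon,
            "trajectories": [
                {"cpg": c, "slope": s, "intercept": b}
                for c, s, b in zip(model.cpg_ids, model.slopes, model.intercepts)
            ],
            "epsilon": model.epsilon,
            "max_missing_frac": model.max_missing_frac,
        }
    else:
        payload = {
            "schema": MODEL_SCHEMA,
            "kind": model.kind,
            "terms": [{"cpg": c, "coef": v} for c, v in model.terms],
            "intercept": model.intercept,
            "meta": model.meta,
        }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model_json(path: str | Path) -> ClockModel | SingleReadModel:
    payload = json.loads(Path(path).read_text())
    schema = payload.get("schema")
    if schema != MODEL_SCHEMA:
        raise ValueError(f"unsupported model schema {schema!r} (expected {MODEL_SCHEMA})")
    if payload["kind"] == "single-read":
        trajs = payload["trajectories"]
        return SingleReadModel(
            amplicon=payload["amplicon"],
            cpg_ids=[t["cpg"] for t in trajs],
            slopes=np.array([t["slope"] for t in trajs]),
            intercepts=np.array([t["intercept"] for t in trajs]),
            epsilon=payload["epsilon"],
            max_missing_frac=payload.get("max_missing_frac", 0.5),
        )
    return ClockModel(
        kind=payload["kind"],
        terms=[(t["cpg"], t["coef"]) for t in payload["terms"]],
        intercept=payload["intercept"],
        meta=payload.get("meta", {}),
    )


# -------------------------------------------------------------- pattern TSV

def write_pattern_tsv(tables: Iterable[ReadPatternTable], path: str | Path) -> None:
    rows = []
    for t in tables:
        for pat in sorted(t.counts):
            rows.append((t.sample_id, t.amplicon, pat, t.counts[pat]))
    df = pd.DataFrame(rows, columns=["sample_id", "amplicon", "pattern", "count"])
    df.to_csv(path, sep="\t", index=False)


def read_pattern_tsv(path: str | Path) -> list[ReadPatternTable]:
    df = pd.read_csv(path, sep="\t", dtype={"pattern": str})
    required = [c for c in ("sample_id", "amplicon", "pattern", "count") if c not in df.columns]
    if required:
        raise ValueError(f"pattern TSV missing required columns: {required}")
    tables = []
    for (sid, amp), grp in df.groupby(["sample_id", "amplicon"], sort=True):
        counts = dict(zip(grp["pattern"], grp["count"].astype(int)))
        n_cpgs = len(next(iter(counts)))
        tables.append(ReadPatternTable(str(sid), str(amp), n_cpgs, counts))
    return tables


# --------------------------------------------------------- distribution CSV

def write_distribution_csv(dists: Sequence[ReadAgeDistribution], path: str | Path) -> None:
    """Samples x 201 grid ages, linear frequencies (log only at plotting)."""
    rows = {f"{d.sample_id}|{d.amplicon}": d.frequencies for d in dists}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"age_{a}" for a in AGE_GRID])
    df.insert(0, "total_reads", [d.total_reads for d in dists])
    df.index.name = "sample_amplicon"
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_distribution_csv(path: str | Path) -> list[ReadAgeDistribution]:
    df = pd.read_csv(path, index_col=0)
    out = []
    for key, row in df.iterrows():
        sid, amp = str(key).split("|", 1)
        freqs = row[[f"age_{a}" for a in AGE_GRID]].to_numpy(dtype=float)
        out.append(ReadAgeDistribution(sid, amp, freqs, int(row["total_reads"])))
    return out


# -------------------------------------------------------------------- panel

def read_panel(path: str | Path) -> list[AmpliconSpec]:
    """Amplicon panel from YAML or JSON: a list of {name, sequence,
    cpg_positions, [max_mismatch_frac], [min_conversion]}."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if isinstance(data, dict) and "amplicons" in data:
        data = data["amplicons"]
    specs = []
    for entry in data:
        specs.append(
            AmpliconSpec(
                name=entry["name"],
                reference_seq=entry["sequence"],
                cpg_positions=tuple(entry["cpg_positions"]),
                max_mismatch_frac=float(entry.get("max_mismatch_frac", 0.1)),
                min_conversion=float(entry.get("min_conversion", 0.9)),
            )
        )
    return specs


def write_panel(specs: Sequence[AmpliconSpec], path: str | Path) -> None:
    data = {
        "amplicons": [
            {
                "name": s.name,
                "sequence": s.reference_seq,
                "cpg_positions": list(s.cpg_positions),
                "max_mismatch_frac": s.max_mismatch_frac,
                "min_conversion": s.min_conversion,
            }
            for s in specs
        ]
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# -------------------------------------------------------------------- FASTQ

def read_fastq_seqs(path: str | Path) -> list[tuple[str, str]]:
    """(read id, sequence) pairs from a FASTQ file, gzipped or plain."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fastq")]
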