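"""Plain-text readers and writers for every format the pipeline touches.

One canonical matrix dialect is used throughout: tab-separated values with a
header row of sample ids and feature ids in the first column.  Spectra are
two-column CSV (ppm, intensity) per sample with a manifest TSV mapping
sample ids to files; term maps are GMT (term, description, members...);
pathway definitions are a GMT dialect whose metabolite members carry a
``met:`` prefix.  All readers report malformed lines with their line number.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fusion import FusionResult
from .synthetic import Sample, StudyDesign

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_spectra",
    "read_spectra",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_gmt",
    "write_gmt",
    "read_pathway_defs",
    "write_pathway_defs",
    "fusion_result_to_json",
    "read_fusion_result_json",
]


def _fail(path: Path | str, lineno: int, msg: str) -> None:
    raise ValueError(f"{path}:{lineno}: {msg}")


def read_spectrum_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read one two-column (ppm, intensity) CSV spectrum."""
    path = Path(path)
    ppm, inten = [], []
    with path.open() as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or (i == 1 and line.lower().startswith("ppm")):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                _fail(path, i, f"expected 2 comma-separated fields, got {len(parts)}")
            try:
                ppm.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError:
                _fail(path, i, f"non-numeric value in {line!r}")
    return np.asarray(ppm), np.asarray(inten)


def write_spectrum_csv(
    path: str | Path, ppm: np.ndarray, intensity: np.ndarray
) -> None:
    with Path(path).open("w") as fh:
        fh.write("ppm,intensity\n")
        for p, y in zip(ppm, intensity):
            fh.write(f"{p:.6g},{y:.10g}\n")


def write_spectra(
    out_dir: str | Path, spectra: dict[str, tuple[np.ndarray, np.ndarray]]
) -> Path:
    """Write one CSV per spectrum plus a manifest TSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "spectra_manifest.tsv"
    with manifest.open("w") as fh:
        fh.write("sample_id\tfile\n")
        for sid, (ppm, inten) in spectra.items():
            fname = f"{sid}.csv"
            write_spectrum_csv(out_dir / fname, ppm, inten)
            fh.write(f"{sid}\t{fname}\n")
    return manifest


def read_spectra(manifest: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    manifest = Path(manifest)
    base = manifest.parent
    out = {}
    with manifest.open() as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or (i == 1 and line.startswith("sample_id")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                _fail(manifest, i, "expected sample_id<TAB>file")
            out[parts[0]] = read_spectrum_csv(base / parts[1])
    return out


def read_matrix_tsv(path: str | Path, dtype=float) -> pd.DataFrame:
    """Read the canonical TSV matrix (features x samples or samples x features)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if dtype is float:
        bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(bad):
            col = bad[0]
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        df = df.astype(float)
    return df


def write_matrix_tsv(path: str | Path, df: pd.DataFrame, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def write_design_tsv(path: str | Path, design: StudyDesign) -> None:
    design.to_frame().to_csv(path, sep="\t")


def read_design_tsv(path: str | Path) -> StudyDesign:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "dose_ppm", "day", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: design table needs columns {sorted(required)}")
    samples = tuple(
        Sample(str(r.sample_id), int(r.dose_ppm), int(r.day), int(r.replicate))
        for r in df.itertuples()
    )
    if len({s.sample_id for s in samples}) != len(samples):
        raise ValueError(f"{path}: duplicate sample ids")
    return StudyDesign(samples=samples)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT term map: term <TAB> description <TAB> member..."""
    path = Path(path)
    out: dict[str, set[str]] = {}
    with path.open() as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                _fail(path, i, "GMT line needs term, description and >= 1 member")
            out[parts[0]] = {m for m in parts[2:] if m}
    return out


def write_gmt(path: str | Path, term_map: dict[str, set[str]], descriptions: dict[str, str] | None = None) -> None:
    with Path(path).open("w") as fh:
        for term in sorted(term_map):
            desc = (descriptions or {}).get(term, "na")
            members = "\t".join(sorted(term_map[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")


def read_pathway_defs(path: str | Path) -> dict[str, tuple[set[str], set[str]]]:
    """GMT dialect with metabolite members prefixed ``met:``.

    Returns pathway -> (gene members, metabolite members).
    """
    raw = read_gmt(path)
    return {
        term: (
            {m for m in members if not m.startswith("met:")},
            {m[4:] for m in members if m.startswith("met:")},
        )
        for term, members in raw.items()
    }


def write_pathway_defs(
    path: str | Path, defs: dict[str, tuple[set[str], set[str]]]
) -> None:
    merged = {
        term: genes | {f"met:{m}" for m in mets} for term, (genes, mets) in defs.items()
    }
    write_gmt(path, merged)


def fusion_result_to_json(res: FusionResult, top_k: int = 25) -> str:
    payload = {
        "metabolite": res.metabolite,
        "n_components": res.n_components,
        "q2": res.q2,
        "permuted_q2": [float(x) for x in res.permuted_q2],
        "passed": res.passed,
        "seed": res.seed,
        "r2y": res.r2y,
        "top_loadings": [
            {"probeset": g, "weight": float(res.loadings[g])}
            for g in res.loadings.index[:top_k]
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def read_fusion_result_json(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return json.load(fh)


def dataclass_to_json(obj) -> str:
    return json.dumps(dataclasses.asdict(obj), indent=2, sort_keys=True, default=str)
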