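"""Tabular and FASTA interchange, run configuration echo, and fixtures.

Interchange format is headered tab-separated text, matching what qPCR
instruments export; sequences travel as FASTA. Non-detect Cq values are kept
explicit (the instrument strings ``Undetermined``/``ND``/empty), never
encoded as 0.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .probe_design import RepeatTarget, default_probe, linearize_to_orf
from .quant_core import ExpCalibration, QPCRRecord, cq_from_copies
from .trf_densitometry import (
    DEFAULT_LADDER_KBP,
    MarkerLadder,
    fit_marker_curve,
    synth_lane,
)

__all__ = [
    "read_qpcr_table",
    "write_qpcr_table",
    "write_results",
    "read_results",
    "write_fasta",
    "read_lane_table",
    "read_ladder_table",
    "make_fixtures",
]

_NON_DETECT = {"", "nan", "na", "nd", "undetermined", "undet", "none"}
_REQUIRED_COLUMNS = ("sample_id", "assay", "cq", "replicate")


def _parse_cq(raw, line_no: int) -> float | None:
    text = str(raw).strip().lower()
    if text in _NON_DETECT:
        return None
    try:
        value = float(text)
    except ValueError:
        raise ValueError(f"line {line_no}: unparseable Cq value {raw!r}") from None
    if np.isnan(value):
        return None
    return value


def read_qpcr_table(path) -> list[QPCRRecord]:
    """Read a tab-separated qPCR export into typed records.

    Requires columns sample_id, assay, cq, replicate. Non-detects
    (``Undetermined``, ``ND``, empty) become ``cq=None``. Duplicate
    (sample_id, assay, replicate) keys and malformed rows are rejected with
    their line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    records: list[QPCRRecord] = []
    seen: dict[tuple, int] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        key = (row["sample_id"], row["assay"], row["replicate"])
        if key in seen:
            raise ValueError(
                f"line {line_no}: duplicate (sample_id, assay, replicate) key "
                f"{key}, first seen on line {seen[key]}"
            )
        seen[key] = line_no
        try:
            replicate = int(row["replicate"])
        except ValueError:
            raise ValueError(
                f"line {line_no}: unparseable replicate {row['replicate']!r}"
            ) from None
        records.append(
            QPCRRecord(
                sample_id=row["sample_id"],
                assay=row["assay"],
                cq=_parse_cq(row["cq"], line_no),
                replicate=replicate,
            )
        )
    return records


def write_qpcr_table(records: Iterable[QPCRRecord], path) -> None:
    """Write records in the same tab-separated layout ``read_qpcr_table`` reads."""
    rows = [
        {
            "sample_id": r.sample_id,
            "assay": r.assay,
            "cq": "Undetermined" if r.cq is None else f"{r.cq:.4f}",
            "replicate": r.replicate,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def write_results(table: pd.DataFrame, path) -> None:
    """Write a tidy result table as tab-separated text (lossless round-trip)."""
    table.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(sequences: dict, path) -> None:
    """Write named sequences to FASTA."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_lane_table(path):
    """Read a two-column (position, od) lane profile table."""
    df = pd.read_csv(path, sep="\t")
    return np.asarray(df.iloc[:, 0], dtype=float), np.asarray(df.iloc[:, 1], dtype=float)


def read_ladder_table(path) -> MarkerLadder:
    """Read a two-column (length_kbp, position) marker ladder table."""
    df = pd.read_csv(path, sep="\t")
    return MarkerLadder(entries=tuple(
        (float(a), float(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    ))


def _default_marker_curve():
    positions = [100.0 - 40.0 * np.log10(L) for L in DEFAULT_LADDER_KBP]
    ladder = MarkerLadder(entries=tuple(zip(DEFAULT_LADDER_KBP, positions)))
    return ladder, fit_marker_curve(ladder)


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Emit a deterministic bundle of worked inputs under ``out_dir``.

    Contents: the published probe and ORF sequences as FASTA; a plasmid
    validation qPCR table whose Cq values regenerate the printed worked
    example (819 and 1590 bp per plasmid copy); a synthetic single-cell
    batch; and a synthetic TRF lane with its marker ladder. Byte-identical
    across runs with the same seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: dict[str, Path] = {}

    probe = default_probe()
    orf = linearize_to_orf(probe)
    fasta = out / "probe_sequences.fasta"
    write_fasta(
        {
            "omega_probe": probe.full_sequence,
            "omega_orf": orf.sequence,
            "telomere_tract_10units": RepeatTarget(n_units=10).tract,
        },
        fasta,
    )
    written["probe_fasta"] = fasta

    # Plasmid worked example: the printed Cq values for the two validation
    # plasmids, one well each, plus a negative control non-detect.
    plasmid = out / "plasmid_validation.tsv"
    write_qpcr_table(
        [
            QPCRRecord("pSXneo135", "omega", 19.380, 1),
            QPCRRecord("pSXneo270", "omega", 17.741, 1),
            QPCRRecord("NTC", "omega", None, 1),
        ],
        plasmid,
    )
    written["plasmid_qpcr"] = plasmid

    # Synthetic single-cell batch: 10 diploid-like cells with total telomere
    # lengths around 500 kb per cell, read out through the default calibration
    # with mild Cq noise.
    cal = ExpCalibration()
    cells = []
    for i in range(10):
        total_tl = float(rng.normal(5.0e5, 3.0e4))
        n_cp = (total_tl - 32.0) / 48.0 + 1.0
        cq = cq_from_copies(n_cp, cal) + float(rng.normal(0.0, 0.05))
        cells.append(QPCRRecord(f"cell{i + 1:02d}", "omega", round(cq, 4), 1))
    single_cell = out / "single_cell_batch.tsv"
    write_qpcr_table(cells, single_cell)
    written["single_cell_qpcr"] = single_cell

    ladder, curve = _default_marker_curve()
    ladder_path = out / "marker_ladder.tsv"
    pd.DataFrame(
        {"length_kbp": ladder.lengths_kbp, "position": ladder.positions}
    ).to_csv(ladder_path, sep="\t", index=False)
    written["ladder"] = ladder_path

    lane = synth_lane(
        curve=curve, mean_log_kbp=np.log(6.0), sd_log_kbp=0.25,
        noise_sd=0.0, seed=seed,
    )
    lane_path = out / "trf_lane.tsv"
    pd.DataFrame({"position": lane.positions, "od": np.round(lane.od, 6)}).to_csv(
        lane_path, sep="\t", index=False
    )
    written["trf_lane"] = lane_path

    manifest = out / "manifest.json"
    manifest.write_text(
        json.dumps({k: p.name for k, p in written.items()}, indent=2) + "\n"
    )
    written["manifest"] = manifest
    return written
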