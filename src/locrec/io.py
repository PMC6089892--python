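"""Readers and writers for the package's text formats.

Formats (all UTF-8, gzip-transparent on input):

* annotation TSV — ``protein_id<TAB>loc1;loc2;...``, ``#`` comment lines;
* pair-score TSV — three columns, plain [0, 1] scores or the STRING-export
  dialect (see :mod:`locrec.similarity`);
* prediction TSV — ``protein_id<TAB>rank<TAB>location<TAB>raw<TAB>normalized``;
* FASTA via Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

from .metrics import MetricsReport
from .recommender import RankedPrediction
from .similarity import _open_text, load_pair_scores, read_fasta  # noqa: F401

__all__ = [
    "read_annotations",
    "write_annotations",
    "read_predictions",
    "write_predictions",
    "write_pair_scores",
    "read_location_list",
    "write_metrics_json",
    "load_pair_scores",
    "read_fasta",
]


def read_annotations(path: str | Path) -> list[tuple[str, frozenset[str]]]:
    """Read a protein→locations table; a protein with no labels is an error."""
    out: list[tuple[str, frozenset[str]]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'protein<TAB>locations'")
            pid = parts[0].strip()
            labels = frozenset(x.strip() for x in parts[1].split(";") if x.strip())
            if not pid:
                raise ValueError(f"{path}:{lineno}: empty protein id")
            if not labels:
                raise ValueError(f"{path}:{lineno}: protein {pid!r} has no locations")
            out.append((pid, labels))
    if not out:
        raise ValueError(f"no annotations found in {path}")
    return out


def write_annotations(
    path: str | Path, annotations: Iterable[tuple[str, Iterable[str]]]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein_id\tlocations\n")
        for pid, labels in annotations:
            fh.write(f"{pid}\t{';'.join(sorted(labels))}\n")


def write_pair_scores(
    path: str | Path, scores: Mapping[tuple[str, str], float]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein_a\tprotein_b\tscore\n")
        for (a, b) in sorted(scores):
            fh.write(f"{a}\t{b}\t{scores[(a, b)]:.6f}\n")


def write_predictions(path: str | Path, predictions: Iterable[RankedPrediction]) -> None:
    """One row per retained location; cold-start queries emit no rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein_id\trank\tlocation\traw_score\tnormalized_score\n")
        for pred in predictions:
            for rank, (loc, raw, norm) in enumerate(pred.entries, start=1):
                fh.write(f"{pred.query_id}\t{rank}\t{loc}\t{raw:.6g}\t{norm:.6g}\n")


def read_predictions(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a prediction TSV back into protein → ordered location list."""
    rows: dict[str, list[tuple[int, str]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 columns")
            pid, rank_s, loc = parts[0], parts[1], parts[2]
            try:
                rank = int(rank_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed rank {rank_s!r}") from None
            rows.setdefault(pid, []).append((rank, loc))
    out: dict[str, tuple[str, ...]] = {}
    for pid, entries in rows.items():
        entries.sort()
        if [r for r, _ in entries] != list(range(1, len(entries) + 1)):
            raise ValueError(f"prediction ranks for {pid!r} are not consecutive from 1")
        out[pid] = tuple(loc for _, loc in entries)
    return out


def read_location_list(path: str | Path) -> tuple[str, ...]:
    """Read a location vocabulary file (one label per line)."""
    labels: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                labels.append(line)
    if not labels:
        raise ValueError(f"no locations found in {path}")
    return tuple(dict.fromkeys(labels))


def write_metrics_json(path: str | Path, report: MetricsReport) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(report.to_json())
        fh.write("\n")
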