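"""File formats: FASTA sequences, TSV label tables, PSPM export.

Sequences are standard FASTA (multi-line records allowed, parsed with
Biopython).  Labels travel in a three-column TSV — sequence id, first
binding label, second binding label — where ``NA`` (case-insensitive) or
an empty field marks an unknown label.  Estimated matrices are written
both as plain TSV (letters as rows, positions as columns; the lossless
primary record) and in MEME minimal motif format so standard logo and
scanning tools can consume them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import UNKNOWN, LabelState, SequenceDataset, PROTEIN_ALPHABET

__all__ = [
    "read_inputs",
    "read_label_table",
    "write_label_table",
    "write_fasta",
    "write_motifs",
    "read_motif_tsv",
    "write_metrics",
    "write_run_summary",
]


class ParseError(ValueError):
    """Malformed input file."""


def _parse_label(token: str, path: str, lineno: int) -> int:
    t = token.strip()
    if t == "" or t.upper() == "NA":
        return UNKNOWN
    if t in ("0", "1"):
        return int(t)
    raise ParseError(f"{path}:{lineno}: illegal label value {token!r} (expected 0, 1 or NA)")


def read_label_table(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read (sequence_id, w, g) rows; NA/empty encodes unknown."""
    ids: list[str] = []
    ws: list[int] = []
    gs: list[int] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if lineno == 1 and parts[0].lower() in ("id", "sequence_id", "seq_id", "name"):
                continue
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}")
            sid = parts[0].strip()
            if sid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate sequence id {sid!r}")
            seen.add(sid)
            ids.append(sid)
            ws.append(_parse_label(parts[1], str(path), lineno))
            gs.append(_parse_label(parts[2], str(path), lineno))
    return ids, np.array(ws, dtype=np.int64), np.array(gs, dtype=np.int64)


def read_inputs(
    fasta_path: str | Path,
    labels_path: str | Path,
    alphabet: str = PROTEIN_ALPHABET,
    p0: float = 0.5,
) -> tuple[SequenceDataset, LabelState]:
    """Load sequences and their label table, matched by identifier."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ParseError(f"{fasta_path}: no FASTA records found")
    rec_ids = [r.id for r in records]
    if len(set(rec_ids)) != len(rec_ids):
        raise ParseError(f"{fasta_path}: duplicate record ids")
    ids, w, g = read_label_table(labels_path)
    by_id = dict(zip(ids, range(len(ids))))
    missing = [rid for rid in rec_ids if rid not in by_id]
    if missing:
        raise ParseError(f"{labels_path}: missing label rows for {missing[:5]}")
    order = [by_id[rid] for rid in rec_ids]
    try:
        data = SequenceDataset([str(r.seq).upper() for r in records], alphabet, ids=rec_ids)
    except Exception as exc:
        raise ParseError(f"{fasta_path}: {exc}") from exc
    return data, LabelState(w[order], g[order], p0)


def write_label_table(path: str | Path, ids: list[str], w: np.ndarray, g: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tw\tg\n")
        for sid, wi, gi in zip(ids, w, g):
            ws = "NA" if wi == UNKNOWN else str(int(wi))
            gs = "NA" if gi == UNKNOWN else str(int(gi))
            fh.write(f"{sid}\t{ws}\t{gs}\n")


def write_fasta(path: str | Path, data: SequenceDataset) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(data.ids, data.sequences):
            fh.write(f">{sid}\n{seq}\n")


def _renormalize(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    sums = matrix.sum(axis=0, keepdims=True)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("matrix columns deviate from the simplex by more than 1e-6")
    return matrix / sums


def _write_pspm_tsv(path: Path, matrix: np.ndarray, alphabet: str) -> None:
    df = pd.DataFrame(matrix, index=list(alphabet),
                      columns=[f"pos{j + 1}" for j in range(matrix.shape[1])])
    df.to_csv(path, sep="\t", float_format="%.12g", index_label="letter")


def read_motif_tsv(path: str | Path) -> tuple[np.ndarray, str]:
    """Read back a PSPM TSV; returns (matrix, alphabet)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), "".join(df.index)


def _write_meme(path: Path, motifs: dict[str, np.ndarray], theta0: np.ndarray,
                alphabet: str, nsites: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {alphabet}\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{c} {p:.6f}" for c, p in zip(alphabet, theta0)) + "\n\n")
        for name, matrix in motifs.items():
            w = matrix.shape[1]
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= {len(alphabet)} w= {w} "
                     f"nsites= {nsites.get(name, 20)} E= 0\n")
            for j in range(w):
                fh.write(" ".join(f"{p:.6f}" for p in matrix[:, j]) + "\n")
            fh.write("\n")


def write_motifs(map_state, out_prefix: str | Path, alphabet: str,
                 nsites_first: int = 0, nsites_second: int = 0) -> list[Path]:
    """Write MAP matrices as TSVs plus one MEME minimal motif file.

    ``map_state`` needs ``theta0``, ``Theta`` and ``ThetaTilde``
    attributes (a chain snapshot or a motif model).  Columns are
    renormalised to sum to one before writing.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    theta0 = _renormalize(np.asarray(map_state.theta0, dtype=float)[:, None])[:, 0]
    Theta = _renormalize(map_state.Theta)
    ThetaTilde = _renormalize(map_state.ThetaTilde)
    paths = []
    for suffix, matrix in (("theta0", theta0[:, None]), ("motif1", Theta), ("motif2", ThetaTilde)):
        p = prefix.with_name(prefix.name + f".{suffix}.tsv")
        _write_pspm_tsv(p, matrix, alphabet)
        paths.append(p)
    meme_path = prefix.with_name(prefix.name + ".meme")
    _write_meme(
        meme_path,
        {"motif1": Theta, "motif2": ThetaTilde},
        theta0,
        alphabet,
        {"motif1": max(nsites_first, 1), "motif2": max(nsites_second, 1)},
    )
    paths.append(meme_path)
    return paths


def write_metrics(path: str | Path, metrics: pd.DataFrame) -> None:
    metrics.to_csv(path, index=False, float_format="%.10g")


def write_run_summary(path: str | Path, summary: dict) -> None:
    def _default(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
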