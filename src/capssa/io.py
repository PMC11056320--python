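"""FASTA ingestion, binary array output, and the JSON sidecar.

Multi-record FASTA files are concatenated in file order into one text
with NO separators between records — suffixes may span record
boundaries, exactly as when a whole genome is indexed as a single text.
Record offsets are retained for provenance.  Output arrays are raw
little-endian unsigned integers of width 4 or 8 bytes per entry, with a
JSON sidecar describing the build.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .pipeline import BuildConfig
from .text import DEFAULT_TERMINATOR, InvalidInputError, Text, build_text

#: Symbols accepted by default (IUPAC nucleotide codes); case-insensitive.
IUPAC = frozenset(b"ACGTURYSWKMBDHVN")

SIDECAR_VERSION = 1


def _p(prefix, ext: str) -> Path:
    return Path(str(prefix) + ext)


def _open_maybe_gzip(path):
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.open(fh))
    return _io.TextIOWrapper(fh)


def read_fasta(path, drop_n: bool = False, unmask: bool = False,
               allow_any: bool = False, terminator=DEFAULT_TERMINATOR):
    """Read a (possibly gzip-compressed, multi-record) FASTA file into a
    single Text.

    ``drop_n`` removes every N/n symbol (runs of unresolved sequence);
    ``unmask`` maps soft-masked lowercase to uppercase.  Non-IUPAC
    symbols raise unless ``allow_any``.  Returns ``(text, info)`` where
    ``info`` records the record ids, their offsets in the concatenated
    body, and the dropped-N count for the sidecar.
    """
    parts = []
    ids = []
    offsets = []
    off = 0
    dropped = 0
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = np.frombuffer(str(rec.seq).encode("ascii"), np.uint8)
            if unmask:
                lower = (seq >= ord("a")) & (seq <= ord("z"))
                seq = np.where(lower, seq - 32, seq).astype(np.uint8)
            if drop_n:
                keep = (seq != ord("N")) & (seq != ord("n"))
                dropped += int(seq.size - keep.sum())
                seq = seq[keep]
            ids.append(rec.id)
            offsets.append(off)
            parts.append(seq)
            off += seq.size
    if not parts:
        raise InvalidInputError(f"no FASTA records found in {path}")
    body = np.concatenate(parts) if parts else np.empty(0, np.uint8)
    if not allow_any and body.size:
        upper = np.where((body >= ord("a")) & (body <= ord("z")),
                         body - 32, body).astype(np.uint8)
        bad = ~np.isin(upper, np.frombuffer(bytes(IUPAC), np.uint8))
        if bad.any():
            sym = chr(int(body[np.flatnonzero(bad)[0]]))
            raise InvalidInputError(
                f"non-IUPAC symbol {sym!r} in {path}; pass allow_any to accept"
            )
    text = build_text(body, terminator=terminator)
    info = {
        "records": ids,
        "record_offsets": offsets,
        "dropped_n": dropped,
        "drop_n": drop_n,
        "unmask": unmask,
    }
    return text, info


def _resolve_width(width, n_entries: int, max_value: int) -> int:
    if width == "auto":
        width = 4 if max_value < 2 ** 32 else 8
    if width not in (4, 8):
        raise InvalidInputError("width must be 4, 8 or 'auto'")
    if width == 4 and max_value >= 2 ** 32:
        raise InvalidInputError(
            "values do not fit in 4-byte entries; rebuild with width=8"
        )
    return width


def write_arrays(sa: np.ndarray, lcp: np.ndarray, prefix, t: Text | None = None,
                 width="auto", config: BuildConfig | None = None,
                 stats=None, extra: dict | None = None) -> dict:
    """Write ``<prefix>.sa`` and ``<prefix>.lcp`` as little-endian
    unsigned fixed-width integers plus a ``<prefix>.json`` sidecar.

    Returns the sidecar dict.  Values too large for ``width`` raise with
    an instruction to use width 8.
    """
    prefix = Path(prefix)
    sa = np.asarray(sa, dtype=np.int64)
    lcp = np.asarray(lcp, dtype=np.int64)
    n = int(sa.shape[0])
    max_value = int(max(sa.max(initial=0), lcp.max(initial=0)))
    width = _resolve_width(width, n, max_value)
    dtype = "<u4" if width == 4 else "<u8"
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sa.astype(dtype).tofile(_p(prefix, ".sa"))
    lcp.astype(dtype).tofile(_p(prefix, ".lcp"))
    sidecar = {
        "format_version": SIDECAR_VERSION,
        "n": n,
        "width": width,
        "text_sha256": hashlib.sha256(t.data.tobytes()).hexdigest() if t is not None else None,
        "config": asdict(config) if config is not None else None,
        "stats": stats.summary() if hasattr(stats, "summary") else stats,
    }
    if extra:
        sidecar.update(extra)
    with open(_p(prefix, ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)
        fh.write("\n")
    return sidecar


def read_arrays(prefix):
    """Read back ``write_arrays`` output; returns ``(sa, lcp, sidecar)``."""
    prefix = Path(prefix)
    with open(_p(prefix, ".json")) as fh:
        sidecar = json.load(fh)
    dtype = "<u4" if sidecar["width"] == 4 else "<u8"
    sa = np.fromfile(_p(prefix, ".sa"), dtype=dtype).astype(np.int64)
    lcp = np.fromfile(_p(prefix, ".lcp"), dtype=dtype).astype(np.int64)
    if sa.shape[0] != sidecar["n"] or lcp.shape[0] != sidecar["n"]:
        raise InvalidInputError("array files do not match sidecar length")
    return sa, lcp, sidecar


def write_fasta(text_or_body, path, record_id="seq", line_width: int = 70) -> None:
    """Write a body (Text sans terminator, bytes, or str) as FASTA."""
    if isinstance(text_or_body, Text):
        body = text_or_body.data[:-1].tobytes().decode("latin-1")
    elif isinstance(text_or_body, (bytes, bytearray)):
        body = bytes(text_or_body).decode("latin-1")
    else:
        body = str(text_or_body)
    with open(path, "w") as fh:
        fh.write(f">{record_id}\n")
        for i in range(0, len(body), line_width):
            fh.write(body[i:i + line_width] + "\n")
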