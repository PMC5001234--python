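"""FASTA input and plain-text motif output."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidInputError
from .simulate import Instance


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, upper-cased sequence) records from a FASTA file.

    Sequence content is not validated here; the solver rejects characters
    outside its alphabet.
    """
    try:
        records = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        ]
    except OSError as exc:
        raise InvalidInputError(f"cannot read FASTA file {path}: {exc}") from exc
    if not records:
        raise InvalidInputError(f"no FASTA records in {path}")
    return records


def write_instance_fasta(instance: Instance, path: str | Path) -> None:
    """Write an instance as FASTA; plant metadata goes into the descriptions."""
    records = []
    for i, s in enumerate(instance.sequences):
        desc = f"l={instance.l} d={instance.d}"
        if instance.planted is not None:
            motif, positions = instance.planted
            desc += f" planted={motif} pos={positions[i]}"
        records.append(SeqRecord(Seq(s), id=f"seq{i + 1}", description=desc))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_motifs(
    motifs: list[str],
    path: str | Path,
    l: int | None = None,
    d: int | None = None,
    n: int | None = None,
    engine: str | None = None,
    seed: int | None = None,
) -> None:
    """One motif per line, lexicographic order, with `#` header comments."""
    with open(path, "w") as fh:
        header = {"l": l, "d": d, "n": n, "engine": engine, "seed": seed}
        for key, value in header.items():
            if value is not None:
                fh.write(f"# {key}={value}\n")
        fh.write(f"# motifs={len(motifs)}\n")
        for motif in motifs:
            fh.write(motif + "\n")


def read_motifs(path: str | Path) -> list[str]:
    """Read a motif list written by :func:`write_motifs` (skips # comments)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
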