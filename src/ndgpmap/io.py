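"""Reading and writing GP maps in the ndgpmap TSV dialect.

Dialect::

    #ndgpmap v1 alphabet=ACGU L=12
    # optional provenance comment lines: "# key=value"
    <genotype>\t<phenotype>\t<probability>

Deterministic maps use the same format with probability 1.0.  Rows for one
genotype need not be contiguous, but a duplicated (genotype, phenotype)
pair is a format error.  Files are UTF-8 with LF line endings.
Probabilities are written with ``repr`` so a write -> read round trip is
exact.
"""

from __future__ import annotations

import re
from pathlib import Path

from .core import DGPMap, GenotypeSpace, NDGPMap, PhenotypeDistribution
from .errors import MapFormatError, MapValidationError

_HEADER_RE = re.compile(r"^#ndgpmap v1 alphabet=(\S+) L=(\d+)\s*$")


def _read_rows(path):
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise MapFormatError(f"{path}: empty file")
    m = _HEADER_RE.match(lines[0])
    if not m:
        raise MapFormatError(
            f"{path}: first line must be '#ndgpmap v1 alphabet=<symbols> L=<int>', "
            f"got {lines[0]!r}"
        )
    space = GenotypeSpace(tuple(m.group(1)), int(m.group(2)))
    metadata: dict[str, str] = {}
    rows: list[tuple[str, str, float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith("#"):
            kv = line.lstrip("#").strip()
            if "=" in kv:
                key, _, value = kv.partition("=")
                metadata[key.strip()] = value.strip()
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise MapFormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
        genotype, phenotype, prob_str = parts
        try:
            prob = float(prob_str)
        except ValueError:
            raise MapFormatError(f"{path}:{lineno}: bad probability {prob_str!r}") from None
        rows.append((genotype, phenotype, prob))
    return space, rows, metadata


def read_ndmap(path, *, renormalize: bool = False, complete: bool | None = None) -> NDGPMap:
    """Read an ND GP map.

    Raises :class:`MapFormatError` on duplicate (genotype, phenotype) rows
    and :class:`MapValidationError` (listing offending genotypes) when a
    genotype's probabilities do not sum to 1 within tolerance, unless
    ``renormalize=True`` is passed explicitly.
    """
    space, rows, metadata = _read_rows(path)
    grouped: dict[str, dict[str, float]] = {}
    for genotype, phenotype, prob in rows:
        probs = grouped.setdefault(genotype, {})
        if phenotype in probs:
            raise MapFormatError(
                f"{path}: duplicate row for genotype {genotype!r}, phenotype {phenotype!r}"
            )
        probs[phenotype] = prob
    table: dict[str, PhenotypeDistribution] = {}
    offenders = []
    for genotype, probs in grouped.items():
        try:
            table[genotype] = PhenotypeDistribution(probs, renormalize=renormalize)
        except MapValidationError:
            offenders.append(genotype)
    if offenders:
        raise MapValidationError(
            f"{path}: non-normalized phenotype distributions for {len(offenders)} genotype(s)",
            offenders=offenders,
        )
    nd = NDGPMap(space, table, complete=complete)
    nd.metadata = metadata
    return nd


def write_ndmap(nd: NDGPMap, path, *, metadata: dict | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#ndgpmap v1 alphabet={''.join(nd.space.alphabet)} L={nd.space.length}\n")
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        for genotype in sorted(nd.table):
            dist = nd.table[genotype]
            for phenotype in sorted(dist.support):
                fh.write(f"{genotype}\t{phenotype}\t{dist[phenotype]!r}\n")


def read_dmap(path, *, complete: bool | None = None) -> DGPMap:
    """Read a deterministic GP map (same dialect, probability 1.0 per row)."""
    space, rows, _metadata = _read_rows(path)
    table: dict[str, str] = {}
    for genotype, phenotype, prob in rows:
        if genotype in table:
            raise MapFormatError(f"{path}: duplicate genotype {genotype!r} in deterministic map")
        if prob != 1.0:
            raise MapValidationError(
                f"{path}: deterministic map row for {genotype!r} has probability {prob!r} != 1.0",
                offenders=[genotype],
            )
        table[genotype] = phenotype
    return DGPMap(space, table, complete=complete)


def write_dmap(d: DGPMap, path, *, metadata: dict | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#ndgpmap v1 alphabet={''.join(d.space.alphabet)} L={d.space.length}\n")
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        for genotype in sorted(d.table):
            fh.write(f"{genotype}\t{d.table[genotype]}\t1.0\n")


def read_fasta_sequences(path) -> list[str]:
    """Plain sequence list from a FASTA file (uppercased, T -> U)."""
    from Bio import SeqIO

    return [str(rec.seq).upper().replace("T", "U") for rec in SeqIO.parse(str(path), "fasta")]
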