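"""Reader/writer for the GenePop genotype interchange format.

The canonical dialect is supported: a free-text title line, locus names
(one per line, or several comma-separated on one line), then population
blocks introduced by a line consisting of ``Pop`` (case-insensitive).
Individual lines are ``<name> , <g1><g2> <g1><g2> ...`` with fixed-width
allele codes (2 or 3 digits per allele) and ``00``/``000`` meaning a
missing allele.

GenePop has no native population names, so site labels ride on the
individual names: ``<site_id>_<index>``.  The site id is everything before
the last underscore (or the full name when there is no underscore).
"""

from __future__ import annotations

import re
from pathlib import Path

from .datatypes import Individual, MicrosatDataset, sorted_call


class GenePopParseError(ValueError):
    pass


_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def _site_of(name: str) -> str:
    return name.rsplit("_", 1)[0] if "_" in name else name


def read_genepop(path: str | Path, allele_digits: int = 3) -> MicrosatDataset:
    """Parse a GenePop file into a :class:`MicrosatDataset`.

    ``allele_digits`` must be 2 or 3; a genotype field therefore has
    ``2 * allele_digits`` characters.  Allele code 0 is the missing
    sentinel; a call is treated as MISSING when either allele is 0.
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenePopParseError("empty file")
    # Title line is lines[0]; locus names run until the first Pop line.
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i].strip()):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if len(set(loci)) != len(loci):
        raise GenePopParseError("duplicate locus names")
    if i >= len(lines) and not loci:
        raise GenePopParseError("no locus names found")

    individuals: list[Individual] = []
    calls: list[list[tuple[int, int] | None]] = []
    width = 2 * allele_digits
    in_pop = False
    pop_count = 0
    pop_size = 0
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if _POP_RE.match(line):
            if in_pop and pop_size == 0:
                raise GenePopParseError(f"empty population block before line {lineno + 1}")
            in_pop = True
            pop_count += 1
            pop_size = 0
            continue
        if not in_pop:
            raise GenePopParseError(f"genotype line before first Pop at line {lineno + 1}")
        if "," not in line:
            raise GenePopParseError(f"missing comma in individual line {lineno + 1}")
        name_part, geno_part = line.split(",", 1)
        name = name_part.strip()
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise GenePopParseError(
                f"line {lineno + 1}: expected {len(loci)} genotype fields, got {len(fields)}"
            )
        row: list[tuple[int, int] | None] = []
        for k, f in enumerate(fields):
            if len(f) != width or not f.isdigit():
                raise GenePopParseError(
                    f"line {lineno + 1}: malformed genotype {f!r} at locus "
                    f"{loci[k]!r} (expected {width} digits)"
                )
            a = int(f[:allele_digits])
            b = int(f[allele_digits:])
            row.append(None if a == 0 or b == 0 else sorted_call(a, b))
        individuals.append(Individual(id=name, site_id=_site_of(name)))
        calls.append(row)
        pop_size += 1
    if in_pop and pop_size == 0:
        raise GenePopParseError("empty final population block")
    return MicrosatDataset(individuals=individuals, loci=loci, calls=calls)


def write_genepop(
    dataset: MicrosatDataset,
    path: str | Path,
    allele_digits: int = 3,
    title: str = "amphigen genotypes",
) -> None:
    """Write the canonical GenePop dialect; inverse of :func:`read_genepop`.

    Individuals are grouped into Pop blocks by site id (order of first
    appearance).  Missing calls are emitted as all-zero fields.
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    limit = 10 ** allele_digits
    for ind, row in zip(dataset.individuals, dataset.calls):
        for call in row:
            if call is not None and (call[0] >= limit or call[1] >= limit):
                raise ValueError(
                    f"individual {ind.id!r}: allele code {max(call)} does not fit "
                    f"in {allele_digits} digits"
                )
    out = [title]
    out.extend(dataset.loci)
    for site in dataset.site_ids:
        out.append("Pop")
        for i in dataset.site_indices(site):
            fields = []
            for call in dataset.calls[i]:
                if call is None:
                    fields.append("0" * (2 * allele_digits))
                else:
                    fields.append(
                        f"{call[0]:0{allele_digits}d}{call[1]:0{allele_digits}d}"
                    )
            out.append(f"{dataset.individuals[i].id} ,  " + " ".join(fields))
    Path(path).write_text("\n".join(out) + "\n")
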