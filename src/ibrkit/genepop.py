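"""Diploid multi-allelic genotype table and GENEPOP I/O.

The GENEPOP dialect supported is the common one: a title line, one locus name
per line (or a single comma-separated line), ``Pop`` markers, and individual
lines ``id ,  aabb aabb ...`` with 2- or 3-digit allele codes per genotype;
``00``/``000`` codes a missing allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, ParameterError

__all__ = ["GenotypeTable", "read_genepop", "write_genepop"]

MISSING = 0  # allele code for a missing allele


@dataclass
class GenotypeTable:
    """Individuals x loci diploid genotype calls with group labels.

    ``calls[i, l]`` is the unordered pair of allele codes (ints >= 1) of
    individual ``i`` at locus ``l``; ``(0, 0)`` marks a missing call.
    """

    individual_ids: list[str]
    group_ids: list[str]  # per individual, parallel to individual_ids
    locus_names: list[str]
    calls: np.ndarray  # (n_individuals, n_loci, 2), int

    _group_index: dict[str, np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int)
        n, m = len(self.individual_ids), len(self.locus_names)
        if m < 1:
            raise ParameterError("need at least one locus")
        if len(self.group_ids) != n:
            raise ParameterError("group_ids must parallel individual_ids")
        if self.calls.shape != (n, m, 2):
            raise ParameterError(
                f"calls must have shape ({n}, {m}, 2), got {self.calls.shape}"
            )
        half = (self.calls == MISSING).sum(axis=2)
        if np.any(half == 1):
            raise ParameterError("half-missing calls are not allowed")
        self._group_index = None

    # -- lookup helpers -----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def groups(self) -> list[str]:
        """Distinct group ids in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.group_ids:
            seen.setdefault(g)
        return list(seen)

    def group_rows(self, group: str) -> np.ndarray:
        """Row indices of the individuals belonging to ``group``."""
        if self._group_index is None:
            idx: dict[str, list[int]] = {}
            for i, g in enumerate(self.group_ids):
                idx.setdefault(g, []).append(i)
            self._group_index = {g: np.array(v) for g, v in idx.items()}
        try:
            return self._group_index[group]
        except KeyError:
            raise ParameterError(f"unknown group {group!r}") from None

    def missing_fraction(self) -> float:
        return float(np.mean(self.calls[:, :, 0] == MISSING))


def read_genepop(path: str | Path) -> GenotypeTable:
    """Read a GENEPOP file into a :class:`GenotypeTable`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: not a GENEPOP file (too short)")
    # locus names: lines 2.. until the first 'Pop'
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if i == len(lines):
        raise FormatError(f"{path}: no 'Pop' line found")
    if not locus_names:
        raise FormatError(f"{path}: no locus names before first 'Pop'")

    ind_ids: list[str] = []
    grp_ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop = 0
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop += 1
            continue
        if "," not in line:
            raise FormatError(f"{path}:{lineno + 1}: expected 'id , genotypes'")
        ind_id, geno = line.split(",", 1)
        fields = geno.split()
        if len(fields) != len(locus_names):
            raise FormatError(
                f"{path}:{lineno + 1}: {len(fields)} genotype fields, "
                f"expected {len(locus_names)}"
            )
        calls: list[tuple[int, int]] = []
        for f in fields:
            if len(f) not in (4, 6) or not f.isdigit():
                raise FormatError(
                    f"{path}:{lineno + 1}: bad genotype field {f!r} "
                    "(need 4 or 6 digits)"
                )
            w = len(f) // 2
            a, b = int(f[:w]), int(f[w:])
            if (a == 0) != (b == 0):
                raise FormatError(f"{path}:{lineno + 1}: half-missing call {f!r}")
            calls.append((a, b))
        ind_ids.append(ind_id.strip())
        grp_ids.append(f"pop{pop}")
        rows.append(calls)
    if not rows:
        raise FormatError(f"{path}: no individuals found")
    return GenotypeTable(
        individual_ids=ind_ids,
        group_ids=grp_ids,
        locus_names=locus_names,
        calls=np.array(rows, dtype=int),
    )


def write_genepop(table: GenotypeTable, path: str | Path, title: str = "ibrkit export") -> None:
    """Write a :class:`GenotypeTable` as GENEPOP with 3-digit allele codes."""
    if int(table.calls.max(initial=0)) > 999:
        raise ParameterError("allele codes above 999 cannot be written as GENEPOP")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(title + "\n")
        for name in table.locus_names:
            fh.write(name + "\n")
        for group in table.groups:
            fh.write("Pop\n")
            for i in table.group_rows(group):
                genos = "".join(
                    f" {a:03d}{b:03d}" for a, b in table.calls[i]
                )
                fh.write(f"{table.individual_ids[i]} ,{genos}\n")
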