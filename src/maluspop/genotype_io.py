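"""Microsatellite genotype containers, GENEPOP I/O and individual-level screening.

Alleles are stored as fragment lengths in nucleotides (not repeat counts), so
single-nucleotide-indel alleles that fall off the repeat-unit lattice are
representable.  Repeat counts, where needed, are derived as
``(length - min_len) / motif_len``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call. Both alleles of a genotype are either
#: missing together or present together; half-missing calls are rejected.
MISSING = -1


class GenepopParseError(ValueError):
    """Raised when a GENEPOP file violates the expected dialect."""


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus: repeat motif and admissible allele window.

    Parameters
    ----------
    name:
        Locus identifier.
    motif_len:
        Repeat-unit length in nucleotides (>= 1).
    n_states:
        Number of contiguous allelic states on the repeat lattice (>= 2).
    min_len:
        Fragment length (nt) of the smallest lattice state.
    """

    name: str
    motif_len: int = 2
    n_states: int = 40
    min_len: int = 100

    def __post_init__(self):
        if self.motif_len < 1:
            raise ValueError(f"{self.name}: motif_len must be >= 1")
        if self.n_states < 2:
            raise ValueError(f"{self.name}: n_states must be >= 2")
        if self.min_len < 1:
            raise ValueError(f"{self.name}: min_len must be >= 1")

    @property
    def max_len(self) -> int:
        """Largest lattice allele length in nucleotides."""
        return self.min_len + self.motif_len * (self.n_states - 1)

    def repeat_count(self, length):
        """Convert allele length(s) in nt to (possibly fractional) repeat counts."""
        return (np.asarray(length, dtype=float) - self.min_len) / self.motif_len


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes: individuals x loci x 2 allele lengths (nt).

    ``calls`` uses :data:`MISSING` for untyped genotypes; a genotype is missing
    at both allele slots or at neither.
    """

    individuals: list[str]
    loci: list[LocusDef]
    calls: np.ndarray  # (n_individuals, n_loci, 2) int32

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)")
        miss = self.calls == MISSING
        if np.any(miss[..., 0] != miss[..., 1]):
            raise ValueError("half-missing genotype: both alleles of a "
                             "genotype must be missing together")
        if np.any((self.calls < 1) & ~miss):
            raise ValueError("non-missing allele lengths must be >= 1")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of loci with a missing genotype."""
        return (self.calls[..., 0] == MISSING).mean(axis=1)

    def subset(self, keep: np.ndarray) -> "GenotypeTable":
        """Return a table restricted to the boolean/index mask ``keep`` (rows)."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeTable(
            individuals=[self.individuals[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
        )

    def locus_alleles(self, j: int) -> np.ndarray:
        """All non-missing allele lengths at locus ``j`` (flattened gene copies)."""
        a = self.calls[:, j, :].ravel()
        return a[a != MISSING]


@dataclass
class PopulationMap:
    """Assignment of every individual to exactly one population label."""

    mapping: dict[str, str]

    def __getitem__(self, ind: str) -> str:
        return self.mapping[ind]

    def __contains__(self, ind: str) -> bool:
        return ind in self.mapping

    def labels(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen = {}
        for p in self.mapping.values():
            seen.setdefault(p, None)
        return list(seen)

    def individuals_in(self, pop: str) -> list[str]:
        return [i for i, p in self.mapping.items() if p == pop]

    def validate(self, table: GenotypeTable) -> None:
        missing = [i for i in table.individuals if i not in self.mapping]
        if missing:
            raise ValueError(f"individuals without population label: {missing[:5]}")


def validate_membership(membership: pd.DataFrame, atol: float = 1e-6) -> None:
    """Check that a membership table has rows summing to 1 with entries in [0,1]."""
    q = membership.to_numpy(dtype=float)
    if np.any(q < -atol) or np.any(q > 1 + atol):
        raise ValueError("membership coefficients must lie in [0, 1]")
    if np.any(np.abs(q.sum(axis=1) - 1.0) > atol):
        raise ValueError("membership rows must sum to 1")


# ---------------------------------------------------------------------------
# GENEPOP dialect
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\b\s*(.*)$", re.IGNORECASE)


def _decode_genotype(field: str, width: int, line_no: int):
    a1 = int(field[:width])
    a2 = int(field[width:])
    if (a1 == 0) != (a2 == 0):
        raise GenepopParseError(
            f"line {line_no}: half-missing genotype {field!r}")
    if a1 == 0:
        return MISSING, MISSING
    return a1, a2


def read_genepop(path, motif_table: dict[str, int] | None = None):
    """Read a GENEPOP file into a (:class:`GenotypeTable`, :class:`PopulationMap`).

    Supports the POP-block dialect: a title line, locus names (one per line or
    comma-separated), ``POP`` separators (optionally ``POP <label>``), and rows
    of the form ``id , a1a2 a1a2 ...`` with 2- or 3-digit allele codes
    (auto-detected); ``000``/``00`` codes mark missing genotypes.  Allele codes
    are read as fragment lengths in nucleotides.

    ``motif_table`` optionally maps locus name -> motif length (nt) for the
    resulting :class:`LocusDef` entries (default motif length 2).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty file")

    # locus names: lines 2.. until first POP line
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = [s.strip() for s in lines[i].split(",") if s.strip()]
        locus_names.extend(chunk)
        i += 1
    if not locus_names:
        raise GenepopParseError("no locus names before first POP line")

    individuals: list[str] = []
    rows: list[list[int]] = []
    pop_of: dict[str, str] = {}
    width: int | None = None
    pop_idx = 0
    cur_pop = None
    for line_no0 in range(i, len(lines)):
        line = lines[line_no0]
        line_no = line_no0 + 1
        if not line.strip():
            continue
        m = _POP_RE.match(line)
        if m:
            pop_idx += 1
            cur_pop = m.group(1).strip() or f"pop_{pop_idx}"
            continue
        if cur_pop is None:
            raise GenepopParseError(f"line {line_no}: data before first POP")
        if "," not in line:
            raise GenepopParseError(f"line {line_no}: missing ',' separator")
        ind_id, _, geno_part = line.partition(",")
        ind_id = ind_id.strip()
        fields = geno_part.split()
        if len(fields) != len(locus_names):
            raise GenepopParseError(
                f"line {line_no}: expected {len(locus_names)} genotype fields, "
                f"found {len(fields)}")
        if width is None:
            flen = len(fields[0])
            if flen not in (4, 6):
                raise GenepopParseError(
                    f"line {line_no}: genotype field {fields[0]!r} is neither "
                    "4 (2-digit) nor 6 (3-digit) characters")
            width = flen // 2
        row: list[int] = []
        for f in fields:
            if len(f) != 2 * width or not f.isdigit():
                raise GenepopParseError(
                    f"line {line_no}: malformed genotype field {f!r}")
            row.extend(_decode_genotype(f, width, line_no))
        individuals.append(ind_id)
        rows.append(row)
        pop_of[ind_id] = cur_pop

    if not individuals:
        raise GenepopParseError("no individuals found")
    motif_table = motif_table or {}
    loci = [LocusDef(name=nm, motif_len=motif_table.get(nm, 2))
            for nm in locus_names]
    calls = np.asarray(rows, dtype=np.int32).reshape(len(individuals),
                                                     len(loci), 2)
    return GenotypeTable(individuals, loci, calls), PopulationMap(pop_of)


def write_genepop(table: GenotypeTable, pops: PopulationMap, path,
                  title: str = "maluspop genotypes") -> None:
    """Write a GENEPOP file (3-digit codes, ``POP <label>`` block headers)."""
    pops.validate(table)
    labels = [pops[i] for i in table.individuals]
    order = []
    seen = {}
    for p in labels:
        seen.setdefault(p, None)
    pop_order = list(seen)
    if not pop_order:
        raise ValueError("cannot write a table with no populations")
    if int(table.calls.max(initial=0)) > 999:
        j = int(np.argwhere(table.calls.max(axis=(0, 2)) > 999)[0, 0])
        raise ValueError(
            f"locus {table.loci[j].name}: allele length exceeds 3-digit code")

    with open(path, "w") as fh:
        fh.write(title + "\n")
        for loc in table.loci:
            fh.write(loc.name + "\n")
        for pop in pop_order:
            fh.write(f"POP {pop}\n")
            for k, ind in enumerate(table.individuals):
                if labels[k] != pop:
                    continue
                codes = []
                for j in range(table.n_loci):
                    a1, a2 = table.calls[k, j]
                    if a1 == MISSING:
                        codes.append("000000")
                    else:
                        codes.append(f"{a1:03d}{a2:03d}")
                fh.write(f"{ind} , " + " ".join(codes) + "\n")


# ---------------------------------------------------------------------------
# Delimited dialect: id, population, then two columns per locus
# ---------------------------------------------------------------------------

def read_table(path, motif_table: dict[str, int] | None = None, sep="\t"):
    """Read the delimited genotype dialect (missing coded as 0)."""
    df = pd.read_csv(path, sep=sep)
    locus_names = [c[:-2] for c in df.columns[2:] if c.endswith("_1")]
    motif_table = motif_table or {}
    loci = [LocusDef(nm, motif_len=motif_table.get(nm, 2)) for nm in locus_names]
    calls = np.empty((len(df), len(loci), 2), dtype=np.int32)
    for j, nm in enumerate(locus_names):
        calls[:, j, 0] = df[f"{nm}_1"].to_numpy()
        calls[:, j, 1] = df[f"{nm}_2"].to_numpy()
    calls[calls == 0] = MISSING
    inds = df.iloc[:, 0].astype(str).tolist()
    pops = PopulationMap(dict(zip(inds, df.iloc[:, 1].astype(str))))
    return GenotypeTable(inds, loci, calls), pops


def write_table(table: GenotypeTable, pops: PopulationMap, path, sep="\t") -> None:
    """Write the delimited genotype dialect (missing coded as 0)."""
    pops.validate(table)
    data = {"id": table.individuals,
            "population": [pops[i] for i in table.individuals]}
    out = np.where(table.calls == MISSING, 0, table.calls)
    for j, loc in enumerate(table.loci):
        data[f"{loc.name}_1"] = out[:, j, 0]
        data[f"{loc.name}_2"] = out[:, j, 1]
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Individual-level screening
# ---------------------------------------------------------------------------

def filter_individuals(table: GenotypeTable, max_missing_frac: float = 0.30,
                       exclude_flags: set[str] | None = None) -> GenotypeTable:
    """Retain individuals with missing fraction strictly below the threshold.

    Individuals listed in ``exclude_flags`` (e.g. known polyploids) are removed
    regardless of missingness.  Order is preserved; the result may be empty.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    exclude_flags = exclude_flags or set()
    frac = table.missing_fraction()
    keep = (frac < max_missing_frac) & np.array(
        [i not in exclude_flags for i in table.individuals])
    return table.subset(keep)


def prune_related(table: GenotypeTable, rxy: pd.DataFrame,
                  threshold: float = 0.5) -> GenotypeTable:
    """Remove individuals until no retained pair has relatedness >= threshold.

    Removal is greedy on the graph joining pairs with ``r_xy >= threshold``:
    repeatedly delete the highest-degree vertex, breaking ties in favour of the
    individual appearing later in the table.
    """
    inds = table.individuals
    if set(rxy.index) != set(inds) or set(rxy.columns) != set(inds):
        raise ValueError("rxy matrix index does not match table individuals")
    r = rxy.loc[inds, inds].to_numpy(dtype=float)
    n = len(inds)
    adj = (r >= threshold)
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    while True:
        deg = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = -1
        dmax = deg.max()
        if dmax <= 0:
            break
        # ties broken by input order: remove the latest max-degree individual
        victim = np.flatnonzero(deg == dmax)[-1]
        alive[victim] = False
    return table.subset(alive)


def screen_admixture(membership: pd.DataFrame, home: dict[str, str],
                     intro_cutoff: float = 0.20,
                     pure_cutoff: float = 0.90) -> pd.Series:
    """Classify individuals from ancestry coefficients of an external clustering.

    Classes (by precedence):

    - ``pure``: membership in the home cluster >= ``pure_cutoff``;
    - ``misclassified``: membership in a single non-home cluster >= ``pure_cutoff``;
    - ``introgressed``: any non-home membership >= ``intro_cutoff``;
    - ``admixed``: none of the above (no single dominant source).
    """
    for c, name in ((intro_cutoff, "intro_cutoff"), (pure_cutoff, "pure_cutoff")):
        if not 0 < c <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    validate_membership(membership)
    out = {}
    for ind, row in membership.iterrows():
        h = home[ind]
        if h not in membership.columns:
            raise ValueError(f"home cluster {h!r} not in membership columns")
        q_home = row[h]
        q_other = row.drop(h)
        if q_home >= pure_cutoff:
            out[ind] = "pure"
        elif (q_other >= pure_cutoff).any():
            out[ind] = "misclassified"
        elif (q_other >= intro_cutoff).any():
            out[ind] = "introgressed"
        else:
            out[ind] = "admixed"
    return pd.Series(out, name="class")
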