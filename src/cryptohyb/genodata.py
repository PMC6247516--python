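"""Core data containers and I/O for genotypes, metadata and aligned sequences.

The central container is :class:`GenotypeMatrix`, an ``n x L x 2`` table of
diploid co-dominant allele calls (microsatellite allele sizes or arbitrary
positive integer codes) with a single missing-data sentinel.  Two text
dialects are supported: a wide CSV with two columns per locus, and the
two-row-per-individual whitespace format used by the major admixture
clustering programs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO

MISSING = -9

Dialect = Literal["csv_wide", "structure_2row"]


class GenotypeFormatError(ValueError):
    """Raised when a genotype file cannot be parsed in the requested dialect."""


class GenotypeValidationError(ValueError):
    """Raised when parsed genotypes violate the diploid call invariants."""


@dataclass
class GenotypeMatrix:
    """Diploid multilocus genotypes for n individuals at L loci.

    Attributes
    ----------
    individual_ids : list of str
        Unique row labels.
    locus_names : list of str
        Unique locus labels, column order preserved from input.
    alleles : ndarray of shape (n, L, 2), dtype int
        Allele codes; both entries of a pair equal ``missing_code`` when the
        genotype failed to amplify.  Non-missing codes are positive.
    missing_code : int
        Sentinel for missing calls (default -9, the convention of the
        clustering programs' input files).
    """

    individual_ids: list[str]
    locus_names: list[str]
    alleles: np.ndarray
    missing_code: int = MISSING

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.locus_names)
        if n < 1 or L < 1:
            raise GenotypeValidationError("need at least one individual and one locus")
        if self.alleles.shape != (n, L, 2):
            raise GenotypeValidationError(
                f"allele array shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        if len(set(self.individual_ids)) != n:
            raise GenotypeValidationError("duplicate individual ids")
        if len(set(self.locus_names)) != L:
            raise GenotypeValidationError("duplicate locus names")
        miss = self.alleles == self.missing_code
        half = miss[:, :, 0] != miss[:, :, 1]
        if half.any():
            i, l = map(int, np.argwhere(half)[0])
            raise GenotypeValidationError(
                "half-missing genotype (one allele of the pair missing) for "
                f"individual {self.individual_ids[i]!r} at locus {self.locus_names[l]!r}"
            )
        bad = ~miss & (self.alleles <= 0)
        if bad.any():
            i, l = map(int, np.argwhere(bad.any(axis=2))[0])
            raise GenotypeValidationError(
                f"non-positive allele code for individual {self.individual_ids[i]!r} "
                f"at locus {self.locus_names[l]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) array, True where the genotype is missing."""
        return self.alleles[:, :, 0] == self.missing_code

    def subset(
        self,
        individuals: Iterable[str] | None = None,
        loci: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given ids / locus names."""
        ids = list(individuals) if individuals is not None else self.individual_ids
        loc = list(loci) if loci is not None else self.locus_names
        ridx = [self.individual_ids.index(i) for i in ids]
        cidx = [self.locus_names.index(l) for l in loc]
        return GenotypeMatrix(
            list(ids), list(loc), self.alleles[np.ix_(ridx, cidx)], self.missing_code
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_names == other.locus_names
            and self.missing_code == other.missing_code
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class SampleMetadata:
    """Per-individual field metadata joined to the genotype matrix by id."""

    individual_id: str
    sex: str = "unknown"  # F, M or unknown
    site: str = ""
    session: str = ""
    forearm_mm: float | None = None
    fme_khz: float | None = None
    flagged_hybrid: bool | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M", "unknown"):
            raise ValueError(f"sex must be F, M or unknown, got {self.sex!r}")
        if self.forearm_mm is not None and not (30 < self.forearm_mm < 100):
            raise ValueError(f"forearm_mm {self.forearm_mm} outside plausible (30, 100) mm")
        if self.fme_khz is not None and not (20 < self.fme_khz < 120):
            raise ValueError(f"fme_khz {self.fme_khz} outside plausible (20, 120) kHz")


@dataclass
class AlignedSequences:
    """Equal-length uppercase DNA sequences over {A, C, G, T, N, -}."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if not self.sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences are not aligned (lengths {sorted(lengths)})")
        if next(iter(lengths)) == 0:
            raise ValueError("zero-length alignment")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ValidationReport:
    """Dataset health summary: amplification rate, allele counts, join issues."""

    n_individuals: int
    n_loci: int
    amplification_rate: float
    per_locus_allele_counts: list[int]
    issues: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genotype I/O


def _parse_intish(tok: str) -> int:
    try:
        return int(tok)
    except ValueError as exc:
        raise GenotypeFormatError(f"non-integer allele code {tok!r}") from exc


def read_genotypes(path: str | Path, dialect: Dialect = "csv_wide") -> GenotypeMatrix:
    """Read a genotype matrix from ``path`` in the given text dialect.

    ``csv_wide``: header ``id,<locus>_a,<locus>_b,...`` with two columns per
    locus.  ``structure_2row``: header-free whitespace table, two consecutive
    rows per individual (one per haploid allele set), first column the id.
    Missing calls are normalised to the -9 sentinel.
    """
    path = Path(path)
    if dialect == "csv_wide":
        return _read_csv_wide(path)
    if dialect == "structure_2row":
        return _read_structure(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv_wide(path: Path) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(t.strip() for t in r)]
    if not rows:
        raise GenotypeFormatError(f"{path}: empty file")
    header = [t.strip() for t in rows[0]]
    if (len(header) - 1) % 2 != 0 or len(header) < 3:
        raise GenotypeFormatError(
            f"{path}: expected an id column plus an even number of allele columns, "
            f"got {len(header)} columns"
        )
    loci = []
    for a_col, b_col in zip(header[1::2], header[2::2]):
        name = a_col[:-2] if a_col.endswith("_a") else a_col
        expect_b = name + "_b" if a_col.endswith("_a") else b_col
        if a_col.endswith("_a") and b_col != expect_b:
            raise GenotypeFormatError(
                f"{path}: allele columns {a_col!r}/{b_col!r} do not pair up"
            )
        loci.append(name)
    ids: list[str] = []
    allele_rows = []
    for row in rows[1:]:
        row = [t.strip() for t in row]
        if len(row) != len(header):
            raise GenotypeFormatError(
                f"{path}: row for {row[0]!r} has {len(row)} fields, expected {len(header)}"
            )
        ids.append(row[0])
        allele_rows.append([_parse_intish(t) for t in row[1:]])
    arr = np.array(allele_rows, dtype=np.int64).reshape(len(ids), len(loci), 2)
    arr[arr <= 0] = MISSING
    return GenotypeMatrix(ids, loci, arr)


def _read_structure(path: Path) -> GenotypeMatrix:
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise GenotypeFormatError(f"{path}: empty file")
    if len(lines) % 2 != 0:
        raise GenotypeFormatError(f"{path}: odd number of rows for a two-row dialect")
    L = len(lines[0]) - 1
    if L < 1:
        raise GenotypeFormatError(f"{path}: no locus columns")
    ids: list[str] = []
    pairs = []
    for r1, r2 in zip(lines[0::2], lines[1::2]):
        if r1[0] != r2[0]:
            raise GenotypeFormatError(
                f"{path}: consecutive rows {r1[0]!r}/{r2[0]!r} are not the same individual"
            )
        if len(r1) != L + 1 or len(r2) != L + 1:
            raise GenotypeFormatError(f"{path}: ragged rows for individual {r1[0]!r}")
        ids.append(r1[0])
        a = [_parse_intish(t) for t in r1[1:]]
        b = [_parse_intish(t) for t in r2[1:]]
        pairs.append(np.stack([a, b], axis=1))
    arr = np.stack(pairs, axis=0)
    arr[arr <= 0] = MISSING
    loci = [f"L{j + 1}" for j in range(L)]
    return GenotypeMatrix(ids, loci, arr)


def write_genotypes(gm: GenotypeMatrix, path: str | Path, dialect: Dialect = "csv_wide") -> None:
    """Write ``gm`` so that :func:`read_genotypes` round-trips it exactly.

    The structure dialect does not carry locus names; round-trip identity for
    it is up to renaming loci ``L1..LL``.
    """
    path = Path(path)
    if dialect == "csv_wide":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["id"]
            for name in gm.locus_names:
                header += [f"{name}_a", f"{name}_b"]
            w.writerow(header)
            for i, ind in enumerate(gm.individual_ids):
                w.writerow([ind] + [int(x) for x in gm.alleles[i].ravel()])
    elif dialect == "structure_2row":
        with open(path, "w") as fh:
            for i, ind in enumerate(gm.individual_ids):
                for c in (0, 1):
                    row = [ind] + [str(int(x)) for x in gm.alleles[i, :, c]]
                    fh.write(" ".join(row) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_fasta(path: str | Path) -> AlignedSequences:
    """Read an aligned FASTA file; lowercase is normalised to uppercase."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return AlignedSequences(ids, seqs)


def write_fasta(seqs: AlignedSequences, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(seqs.ids, seqs.sequences):
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# validation


def validate_dataset(
    gm: GenotypeMatrix, metadata: list[SampleMetadata] | None = None
) -> ValidationReport:
    """Summarise dataset health without raising.

    Reports the mean amplification rate ``1 - missing/(n*L)``, the number of
    distinct non-missing alleles per locus, and metadata join problems
    (metadata rows whose id matches no genotyped individual).
    """
    miss = gm.missing_mask
    amp = 1.0 - miss.sum() / miss.size
    counts = []
    for l in range(gm.n_loci):
        col = gm.alleles[:, l, :]
        counts.append(int(len(np.unique(col[col != gm.missing_code]))))
    issues: list[str] = []
    if metadata is not None:
        known = set(gm.individual_ids)
        seen: set[str] = set()
        for m in metadata:
            if m.individual_id not in known:
                issues.append(f"metadata id {m.individual_id!r} matches no genotyped individual")
            if m.individual_id in seen:
                issues.append(f"duplicate metadata row for {m.individual_id!r}")
            seen.add(m.individual_id)
        for ind in gm.individual_ids:
            if ind not in seen:
                issues.append(f"individual {ind!r} has no metadata row")
    for l, c in enumerate(counts):
        if c == 0:
            issues.append(f"locus {gm.locus_names[l]!r} is entirely missing")
    return ValidationReport(
        n_individuals=gm.n_individuals,
        n_loci=gm.n_loci,
        amplification_rate=float(amp),
        per_locus_allele_counts=counts,
        issues=issues,
    )


def metadata_to_frame(metadata: list[SampleMetadata]):
    """Convenience: metadata rows as a pandas DataFrame indexed by id."""
    import pandas as pd

    return pd.DataFrame(
        {
            "individual_id": [m.individual_id for m in metadata],
            "sex": [m.sex for m in metadata],
            "site": [m.site for m in metadata],
            "session": [m.session for m in metadata],
            "forearm_mm": [m.forearm_mm for m in metadata],
            "fme_khz": [m.fme_khz for m in metadata],
            "flagged_hybrid": [m.flagged_hybrid for m in metadata],
        }
    ).set_index("individual_id")
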