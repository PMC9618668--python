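"""Haplotype and frequency-table I/O, haplotype assignment, fragment harmonization.

Mixed stock analysis of mtDNA control-region data runs off three kinds of input:
a reference set of named haplotype sequences (FASTA), a baseline table of
per-rookery haplotype counts with rookery covariates, and one table of haplotype
counts per sampled mixed aggregation.  Published rookery baselines are mostly
short (~500 bp) control-region fragments while newer surveys sequence longer
(~800-950 bp) fragments, so sequences must be truncated to a common window and
haplotypes that become indistinguishable on that window collapsed into one
frequency class before the two tables can share a haplotype axis.

Table dialect
-------------
Delimited text (comma or tab, autodetected).  First column: unit code (rookery
or mixed-stock code).  Remaining headers are haplotype names, except the
reserved header ``SIZE`` (rookery size, nests/year) and headers of the form
``P_<stockcode>`` (probability of transport by ocean currents from the rookery
to that sampled stock).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "ValidationError",
    "HaplotypeRecord",
    "BaselineTable",
    "MixedStockTable",
    "Assignment",
    "read_fasta",
    "write_fasta",
    "read_baseline_table",
    "write_baseline_table",
    "read_mixed_table",
    "write_mixed_table",
    "match_haplotype",
    "collapse_to_short_classes",
    "harmonize",
]

logger = logging.getLogger("mixedstock")

#: IUPAC nucleotide one-letter codes (ambiguity codes are ordinary characters
#: here, never wildcards: named haplotypes are defined by exact sequence).
IUPAC_CHARS = frozenset("ACGTURYSWKMBDHVN")
GAP_CHARS = frozenset("-.~")

#: Two-letter codes for the seven extant sea turtle species.
SPECIES_CODES = ("Cm", "Cc", "Ei", "Lo", "Lk", "Nd", "Dc")

SIZE_COLUMN = "SIZE"
TRANSPORT_PREFIX = "P_"


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input violates a table or sequence invariant."""


def _clean_sequence(seq: str) -> str:
    """Uppercase and strip gap characters and surrounding whitespace."""
    return "".join(ch for ch in seq.strip().upper() if ch not in GAP_CHARS)


def _check_alphabet(name: str, seq: str) -> None:
    bad = set(seq) - IUPAC_CHARS
    if bad:
        raise ValidationError(
            f"sequence {name!r} contains non-IUPAC characters: {sorted(bad)}"
        )


@dataclass
class HaplotypeRecord:
    """A named control-region haplotype sequence.

    ``fragment_class`` distinguishes the short (~500 bp or less) fragments that
    dominate the older rookery literature from the long (>700 bp) fragments
    produced by newer primer pairs; thresholds are configurable via
    :meth:`classify_fragment`.
    """

    name: str
    sequence: str
    species: str | None = None
    fragment_class: str | None = None
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("haplotype record requires a non-empty name")
        core = self.core_sequence
        if not core:
            raise ValidationError(f"haplotype {self.name!r}: empty sequence after gap stripping")
        _check_alphabet(self.name, core)
        if self.species is not None and self.species not in SPECIES_CODES:
            raise ValidationError(
                f"haplotype {self.name!r}: unknown species code {self.species!r} "
                f"(expected one of {SPECIES_CODES})"
            )
        if self.fragment_class not in (None, "short", "long"):
            raise ValidationError(
                f"haplotype {self.name!r}: fragment_class must be 'short' or 'long'"
            )

    @property
    def core_sequence(self) -> str:
        """Sequence uppercased with gap characters removed."""
        return _clean_sequence(self.sequence)

    def classify_fragment(self, short_max: int = 500, long_min: int = 700) -> str:
        """Assign ``short``/``long`` from the gap-stripped length."""
        n = len(self.core_sequence)
        if n <= short_max:
            return "short"
        if n > long_min:
            return "long"
        return "intermediate"


def read_fasta(path: str | Path, meta_delimiter: str = "|") -> list[HaplotypeRecord]:
    """Read haplotype reference sequences from FASTA.

    Headers may carry metadata after ``meta_delimiter``:
    ``>name|species|fragment_class`` (both metadata fields optional).
    Duplicate names raise :class:`ValidationError`.
    """
    path = Path(path)
    records: list[HaplotypeRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython error text varies
        raise ParseError(f"{path}: not parseable as FASTA: {exc}") from exc
    if not parsed:
        # biopython silently yields nothing for non-FASTA text; locate the issue
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip():
                    if not line.startswith(">"):
                        raise ParseError(f"{path}:{lineno}: expected FASTA header, got {line.strip()!r}")
                    break
    for rec in parsed:
        parts = rec.description.split(meta_delimiter)
        name = parts[0].strip().split()[0] if parts[0].strip() else ""
        species = parts[1].strip() or None if len(parts) > 1 else None
        frag = parts[2].strip() or None if len(parts) > 2 else None
        if name in seen:
            raise ValidationError(f"{path}: duplicate haplotype name {name!r}")
        seen.add(name)
        records.append(
            HaplotypeRecord(name=name, sequence=str(rec.seq).upper(), species=species, fragment_class=frag)
        )
    return records


def write_fasta(records: Iterable[HaplotypeRecord], path: str | Path, meta_delimiter: str = "|") -> None:
    """Write records in the same header dialect :func:`read_fasta` reads."""
    out = []
    for rec in records:
        header = rec.name
        if rec.species or rec.fragment_class:
            header += meta_delimiter + (rec.species or "")
        if rec.fragment_class:
            header += meta_delimiter + rec.fragment_class
        out.append(SeqRecord(Seq(rec.core_sequence), id=header, description=""))
    SeqIO.write(out, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


def _validate_counts(codes: Sequence[str], names: Sequence[str], counts: np.ndarray, kind: str) -> None:
    if len(set(codes)) != len(codes):
        raise ValidationError(f"{kind}: duplicate unit codes")
    if len(set(names)) != len(names):
        raise ValidationError(f"{kind}: duplicate haplotype names")
    if counts.shape != (len(codes), len(names)):
        raise ValidationError(
            f"{kind}: count matrix shape {counts.shape} does not match "
            f"{len(codes)} units x {len(names)} haplotypes"
        )
    if np.any(counts < 0):
        bad = [codes[i] for i in np.unique(np.nonzero(counts < 0)[0])]
        raise ValidationError(f"{kind}: negative counts in rows {bad}")
    sums = counts.sum(axis=1)
    if np.any(sums == 0):
        bad = [codes[i] for i in np.nonzero(sums == 0)[0]]
        raise ValidationError(f"{kind}: zero-sum rows for units {bad}")


@dataclass
class BaselineTable:
    """Per-rookery haplotype counts with rookery covariates.

    ``X[r, h]`` is the number of sampled individuals at rookery ``r`` carrying
    haplotype ``h``; ``N[r]`` is the rookery size in nests/year; ``p[r, m]`` is
    the probability of passive transport by ocean currents from rookery ``r``
    to sampled mixed stock ``m`` (columns ordered as ``p_stocks``).
    """

    rookery_codes: list[str]
    haplotype_names: list[str]
    X: np.ndarray
    N: np.ndarray
    p: np.ndarray | None = None
    p_stocks: list[str] | None = None
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int64)
        self.N = np.asarray(self.N, dtype=float)
        if self.p is not None:
            self.p = np.asarray(self.p, dtype=float)
        if not self.validate:
            return
        _validate_counts(self.rookery_codes, self.haplotype_names, self.X, "baseline")
        if self.N.shape != (len(self.rookery_codes),):
            raise ValidationError("baseline: SIZE vector length mismatch")
        if np.any(~np.isfinite(self.N)) or np.any(self.N <= 0):
            raise ValidationError("baseline: rookery sizes must be strictly positive")
        if self.p is not None:
            if self.p_stocks is None:
                raise ValidationError("baseline: transport matrix present but p_stocks missing")
            if self.p.shape != (len(self.rookery_codes), len(self.p_stocks)):
                raise ValidationError("baseline: transport matrix shape mismatch")
            if np.any(self.p < 0) or np.any(self.p > 1):
                raise ValidationError("baseline: transport probabilities must lie in [0, 1]")
            if np.any(self.p.sum(axis=1) > 1 + 1e-6):
                bad = [self.rookery_codes[i] for i in np.nonzero(self.p.sum(axis=1) > 1 + 1e-6)[0]]
                raise ValidationError(f"baseline: transport rows exceed 1 for {bad}")

    @property
    def R(self) -> int:
        return len(self.rookery_codes)

    @property
    def H(self) -> int:
        return len(self.haplotype_names)

    def subset(self, keep: Sequence[int]) -> "BaselineTable":
        keep = list(keep)
        return BaselineTable(
            rookery_codes=[self.rookery_codes[i] for i in keep],
            haplotype_names=list(self.haplotype_names),
            X=self.X[keep],
            N=self.N[keep],
            p=None if self.p is None else self.p[keep],
            p_stocks=None if self.p_stocks is None else list(self.p_stocks),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=self.rookery_codes, columns=self.haplotype_names)
        df.insert(0, SIZE_COLUMN, self.N)
        if self.p is not None:
            for j, stock in enumerate(self.p_stocks):
                df[f"{TRANSPORT_PREFIX}{stock}"] = self.p[:, j]
        df.index.name = "code"
        return df


@dataclass
class MixedStockTable:
    """Per-mixed-stock haplotype counts of sampled individuals."""

    stock_codes: list[str]
    haplotype_names: list[str]
    Y: np.ndarray
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int64)
        if self.validate:
            _validate_counts(self.stock_codes, self.haplotype_names, self.Y, "mixed-stock")

    @property
    def M(self) -> int:
        return len(self.stock_codes)

    @property
    def H(self) -> int:
        return len(self.haplotype_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Y, index=self.stock_codes, columns=self.haplotype_names)
        df.index.name = "code"
        return df


def _read_delimited(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype={0: str})
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as a delimited table: {exc}") from exc
    df.index = df.index.astype(str)
    return df


def read_baseline_table(path: str | Path) -> BaselineTable:
    """Read a rookery baseline table (dialect in the module docstring)."""
    df = _read_delimited(path)
    if SIZE_COLUMN not in df.columns:
        raise ValidationError(f"{path}: missing reserved column {SIZE_COLUMN!r}")
    p_cols = [c for c in df.columns if c.startswith(TRANSPORT_PREFIX)]
    hap_cols = [c for c in df.columns if c != SIZE_COLUMN and c not in p_cols]
    counts = df[hap_cols].to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or np.any(counts != np.floor(counts)):
        raise ValidationError(f"{path}: haplotype counts must be integers")
    return BaselineTable(
        rookery_codes=list(df.index),
        haplotype_names=hap_cols,
        X=counts.astype(np.int64),
        N=df[SIZE_COLUMN].to_numpy(dtype=float),
        p=df[p_cols].to_numpy(dtype=float) if p_cols else None,
        p_stocks=[c[len(TRANSPORT_PREFIX):] for c in p_cols] if p_cols else None,
    )


def write_baseline_table(table: BaselineTable, path: str | Path, sep: str = ",") -> None:
    table.to_frame().to_csv(path, sep=sep)


def read_mixed_table(path: str | Path) -> MixedStockTable:
    """Read a mixed-stock count table (same dialect, no covariate columns)."""
    df = _read_delimited(path)
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or np.any(counts != np.floor(counts)):
        raise ValidationError(f"{path}: haplotype counts must be integers")
    return MixedStockTable(
        stock_codes=list(df.index),
        haplotype_names=list(df.columns),
        Y=counts.astype(np.int64),
    )


def write_mixed_table(table: MixedStockTable, path: str | Path, sep: str = ",") -> None:
    table.to_frame().to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# haplotype assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Assignment:
    """Result of matching a query sequence against a reference set.

    ``kind`` is ``"match"`` (exactly one identical reference over the overlap),
    ``"ambiguous"`` (several references identical over the overlap, typically a
    short query against long references), or ``"orphan"`` (no identity).
    """

    kind: str
    names: tuple[str, ...]

    @property
    def name(self) -> str:
        if self.kind != "match":
            raise ValueError(f"assignment is {self.kind}, not a unique match")
        return self.names[0]


def match_haplotype(
    query: str,
    references: Sequence[HaplotypeRecord],
    min_overlap: int = 400,
) -> Assignment:
    """Assign a query sequence to known haplotypes by literal identity.

    Sequences are assumed to start at the same primer position, so the overlap
    of a query with a reference is the first ``min(len(query), len(ref))``
    positions after gap stripping and uppercasing.  Identity over the full
    overlap is required; IUPAC ambiguity codes are compared as ordinary
    characters.  Overlap below ``min_overlap`` is an error, not an orphan call.
    """
    q = _clean_sequence(query)
    _check_alphabet("<query>", q)
    if not references:
        raise ValueError("empty reference set")
    hits: list[str] = []
    for ref in references:
        ref_seq = ref.core_sequence
        overlap = min(len(q), len(ref_seq))
        if overlap < min_overlap:
            raise ValidationError(
                f"overlap of query with reference {ref.name!r} is {overlap} nt "
                f"(< minimum {min_overlap})"
            )
        if q[:overlap] == ref_seq[:overlap]:
            hits.append(ref.name)
    if len(hits) == 1:
        return Assignment("match", (hits[0],))
    if hits:
        return Assignment("ambiguous", tuple(sorted(hits)))
    return Assignment("orphan", ())


def collapse_to_short_classes(
    records: Sequence[HaplotypeRecord],
    window: tuple[int, int] = (0, 490),
) -> dict[str, list[str]]:
    """Partition haplotype names into short-fragment equivalence classes.

    ``window`` is a half-open 0-based interval on the aligned fragment; names
    whose truncated sequences are literally identical fall into one class.
    Class labels are the lexicographically smallest member name, so the
    partition is deterministic.  Records shorter than the window are an error.
    """
    start, stop = window
    if not (0 <= start < stop):
        raise ValueError(f"invalid truncation window {window}")
    too_short = [r.name for r in records if len(r.core_sequence) < stop]
    if too_short:
        raise ValidationError(
            f"records shorter than truncation window [{start}, {stop}): {too_short}"
        )
    groups: dict[str, list[str]] = {}
    for rec in records:
        groups.setdefault(rec.core_sequence[start:stop], []).append(rec.name)
    partition = {min(names): sorted(names) for names in groups.values()}
    return dict(sorted(partition.items()))


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


def _class_map(classes: dict[str, list[str]] | None, names: Iterable[str]) -> dict[str, str]:
    if classes is None:
        return {n: n for n in names}
    mapping: dict[str, str] = {}
    for label, members in classes.items():
        for member in members:
            if member in mapping:
                raise ValidationError(f"haplotype {member!r} appears in more than one class")
            mapping[member] = label
    missing = [n for n in names if n not in mapping]
    if missing:
        raise ValidationError(f"haplotypes not covered by any class: {missing}")
    return mapping


def harmonize(
    baseline: BaselineTable,
    mixed: MixedStockTable,
    classes: dict[str, list[str]] | None = None,
    on_orphan: str = "error",
) -> tuple[BaselineTable, MixedStockTable]:
    """Collapse both tables onto one shared, ordered haplotype-class axis.

    Counts of same-class haplotypes are summed; total counts are conserved
    exactly.  A mixed-stock haplotype class absent from every rookery baseline
    (an "orphan") leaves the mixture likelihood undefined, so the default is a
    hard error; ``on_orphan="drop"`` instead removes those individuals with a
    logged warning.
    """
    if on_orphan not in ("error", "drop"):
        raise ValueError("on_orphan must be 'error' or 'drop'")
    mapping = _class_map(classes, list(baseline.haplotype_names) + list(mixed.haplotype_names))

    labels: list[str] = []
    for name in list(baseline.haplotype_names) + list(mixed.haplotype_names):
        label = mapping[name]
        if label not in labels:
            labels.append(label)
    index = {label: j for j, label in enumerate(labels)}

    Xc = np.zeros((baseline.R, len(labels)), dtype=np.int64)
    for j, name in enumerate(baseline.haplotype_names):
        Xc[:, index[mapping[name]]] += baseline.X[:, j]
    Yc = np.zeros((mixed.M, len(labels)), dtype=np.int64)
    for j, name in enumerate(mixed.haplotype_names):
        Yc[:, index[mapping[name]]] += mixed.Y[:, j]

    orphan = (Xc.sum(axis=0) == 0) & (Yc.sum(axis=0) > 0)
    if np.any(orphan):
        names = [labels[j] for j in np.nonzero(orphan)[0]]
        if on_orphan == "error":
            raise ValidationError(
                f"orphan haplotype classes absent from every baseline: {names}"
            )
        dropped = int(Yc[:, orphan].sum())
        logger.warning(
            "dropping %d mixed-stock individuals with orphan haplotypes %s", dropped, names
        )
        keep = ~orphan
        labels = [l for l, k in zip(labels, keep) if k]
        Xc = Xc[:, keep]
        Yc = Yc[:, keep]

    new_baseline = replace(baseline, haplotype_names=list(labels), X=Xc)
    new_mixed = replace(mixed, haplotype_names=list(labels), Y=Yc)
    return new_baseline, new_mixed
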