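"""Haplotype-registry curation: deduplication, name disambiguation, metadata gaps.

Control-region haplotypes accumulate in the literature under inconsistent
names: the same sequence published under two names, or two distinct sequences
published under one name.  This module applies deterministic curation rules to
a registry of named sequences with author/year/basin/life-stage metadata and
computes a presence matrix (distinct haplotypes per species x life stage x
ocean basin) whose empty cells are the sampling gaps.

Life stages are binned into five categories based on the size and location of
the encountered turtles; strandings are assumed to occur near foraging sites
and therefore bin with in-water adults.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hapio import HaplotypeRecord, ValidationError, _clean_sequence, read_fasta, write_fasta

__all__ = [
    "LIFE_STAGE_BINS",
    "BASINS",
    "RegistryRecord",
    "CuratedHaplotype",
    "PresenceMatrix",
    "bin_life_stage",
    "dedupe",
    "disambiguate",
    "presence_matrix",
    "gap_report",
    "read_registry",
    "write_registry",
]

logger = logging.getLogger("mixedstock")

DISPERSAL = "dispersal-stage juvenile"
POST_DISPERSAL = "post-dispersal juvenile"
MIXED_STAGE = "mixed post-dispersal juvenile/in-water adult"
IN_WATER_ADULT = "in-water adult"
ROOKERY = "rookery"

#: The five life-stage bins, in life-cycle order.
LIFE_STAGE_BINS = (DISPERSAL, POST_DISPERSAL, MIXED_STAGE, IN_WATER_ADULT, ROOKERY)

#: Ocean basins at default recording granularity.
BASINS = ("Atlantic", "Mediterranean", "Indian", "Pacific")

#: Controlled vocabulary mapping raw stage descriptions to the five bins.
#: Strandings are assumed to occur near foraging sites (in-water adults).
_STAGE_VOCAB = {
    "dispersal juvenile": DISPERSAL,
    "dispersal-stage juvenile": DISPERSAL,
    "oceanic juvenile": DISPERSAL,
    "post-hatchling": DISPERSAL,
    "lost years": DISPERSAL,
    "post-dispersal juvenile": POST_DISPERSAL,
    "neritic juvenile": POST_DISPERSAL,
    "coastal juvenile": POST_DISPERSAL,
    "foraging juvenile": POST_DISPERSAL,
    "mixed juvenile/adult": MIXED_STAGE,
    "mixed foraging aggregation": MIXED_STAGE,
    "mixed post-dispersal juvenile/in-water adult": MIXED_STAGE,
    "in-water adult": IN_WATER_ADULT,
    "foraging adult": IN_WATER_ADULT,
    "stranding": IN_WATER_ADULT,
    "stranding near foraging site": IN_WATER_ADULT,
    "rookery": ROOKERY,
    "nesting female": ROOKERY,
    "nesting beach": ROOKERY,
    "egg": ROOKERY,
    "hatchling": ROOKERY,
}


def bin_life_stage(raw: str) -> str:
    """Map a raw life-stage description to one of the five bins.

    Unmapped terms raise :class:`ValidationError` naming the term; silent
    guessing would corrupt the gap analysis.
    """
    key = raw.strip().lower()
    if key in _STAGE_VOCAB:
        return _STAGE_VOCAB[key]
    raise ValidationError(
        f"unmapped life-stage term {raw!r}; known terms: {sorted(_STAGE_VOCAB)}"
    )


@dataclass
class RegistryRecord:
    """One literature entry: a named sequence plus its publication metadata."""

    name: str
    sequence: str
    species: str
    author: str = ""
    year: int | None = None
    basins: tuple[str, ...] = ()
    life_stages: tuple[str, ...] = ()
    citation: str = ""

    def __post_init__(self) -> None:
        bad = [b for b in self.basins if b not in BASINS]
        if bad:
            raise ValidationError(f"record {self.name!r}: unknown basins {bad}")
        self.life_stages = tuple(
            s if s in LIFE_STAGE_BINS else bin_life_stage(s) for s in self.life_stages
        )

    @property
    def core_sequence(self) -> str:
        return _clean_sequence(self.sequence)


@dataclass
class CuratedHaplotype:
    """A deduplicated haplotype with merged metadata and synonym list."""

    name: str
    sequence: str
    species: str
    synonyms: tuple[str, ...] = ()
    basins: tuple[str, ...] = ()
    life_stages: tuple[str, ...] = ()
    citations: tuple[str, ...] = ()


def _name_prefix(name: str) -> str:
    """Nomenclature prefix: leading characters up to the first digit."""
    m = re.match(r"\D*", name)
    return m.group(0)


def _canonical_order(records: Sequence[RegistryRecord]) -> dict[str, tuple]:
    """Sort key implementing the canonical-name rule.

    Prefer the name whose prefix matches the species' dominant nomenclature
    prefix, then the earliest publication year, then lexicographic order.
    A deterministic approximation of "most consistent with others for the
    species"; merges are logged so the choice is auditable.
    """
    prefixes = pd.Series([_name_prefix(r.name) for r in records])
    dominant = prefixes.mode().iloc[0] if len(prefixes) else ""
    return {
        r.name: (_name_prefix(r.name) != dominant, r.year if r.year is not None else np.inf, r.name)
        for r in records
    }


def dedupe(
    records: Sequence[RegistryRecord],
) -> tuple[list[CuratedHaplotype], dict[str, list[str]]]:
    """Merge records with identical sequences into curated haplotypes.

    Records must belong to one species and comparable fragment class.  Returns
    the curated set plus a synonym map (canonical name -> merged names).
    Idempotent: running dedupe on its own output changes nothing.
    """
    species = {r.species for r in records}
    if len(species) > 1:
        raise ValidationError(f"dedupe expects records of one species, got {sorted(species)}")
    groups: dict[str, list[RegistryRecord]] = {}
    order: list[str] = []
    for rec in records:
        key = rec.core_sequence
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(rec)
    rank = _canonical_order(records)
    curated: list[CuratedHaplotype] = []
    synonym_map: dict[str, list[str]] = {}
    for key in order:
        members = groups[key]
        names = sorted({m.name for m in members}, key=lambda n: rank[n])
        canonical = names[0]
        if len(names) > 1:
            logger.info("merging identical sequences %s -> %s", names[1:], canonical)
        synonym_map[canonical] = names[1:]
        curated.append(CuratedHaplotype(
            name=canonical,
            sequence=key,
            species=members[0].species,
            synonyms=tuple(names[1:]),
            basins=tuple(sorted({b for m in members for b in m.basins})),
            life_stages=tuple(sorted({s for m in members for s in m.life_stages},
                                     key=LIFE_STAGE_BINS.index)),
            citations=tuple(sorted({m.citation for m in members if m.citation})),
        ))
    return curated, synonym_map


def disambiguate(records: Sequence[RegistryRecord]) -> list[RegistryRecord]:
    """Resolve name collisions between distinct sequences.

    When two unique sequences share a name, each colliding record is renamed
    ``<name>_<author>``.  A collision between distinct sequences with the same
    author cannot be resolved and raises.
    """
    by_name: dict[str, list[RegistryRecord]] = {}
    for rec in records:
        by_name.setdefault(rec.name, []).append(rec)
    out: list[RegistryRecord] = []
    for name, group in by_name.items():
        distinct = {g.core_sequence for g in group}
        if len(distinct) == 1:
            out.extend(group)
            continue
        authors = [g.author for g in group]
        seq_of_author: dict[str, str] = {}
        for g in group:
            prev = seq_of_author.setdefault(g.author, g.core_sequence)
            if prev != g.core_sequence:
                raise ValidationError(
                    f"cannot disambiguate {name!r}: distinct sequences share author {g.author!r}"
                )
        logger.info("renaming colliding haplotype %r published by %s", name, sorted(set(authors)))
        for g in group:
            out.append(replace(g, name=f"{name}_{g.author}"))
    return out


@dataclass
class PresenceMatrix:
    """Distinct-haplotype counts per (species, life stage[, basin]) cell."""

    species: list[str]
    life_stages: list[str]
    basins: list[str] | None
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        if self.basins is None:
            return pd.DataFrame(self.counts, index=self.species, columns=self.life_stages)
        idx = pd.MultiIndex.from_product([self.species, self.basins], names=["species", "basin"])
        return pd.DataFrame(self.counts.reshape(-1, len(self.life_stages)), index=idx,
                            columns=self.life_stages)


def presence_matrix(
    curated: Sequence[CuratedHaplotype],
    species: Sequence[str] | None = None,
    by_basin: bool = False,
) -> PresenceMatrix:
    """Count distinct haplotypes observed in each metadata cell."""
    if species is None:
        species = sorted({c.species for c in curated})
    stages = list(LIFE_STAGE_BINS)
    if by_basin:
        counts = np.zeros((len(species), len(BASINS), len(stages)), dtype=np.int64)
        for c in curated:
            if c.species not in species:
                continue
            i = list(species).index(c.species)
            for b in c.basins:
                for s in c.life_stages:
                    counts[i, BASINS.index(b), stages.index(s)] += 1
        return PresenceMatrix(list(species), stages, list(BASINS), counts)
    counts = np.zeros((len(species), len(stages)), dtype=np.int64)
    for c in curated:
        if c.species not in species:
            continue
        i = list(species).index(c.species)
        for s in c.life_stages:
            counts[i, stages.index(s)] += 1
    return PresenceMatrix(list(species), stages, None, counts)


def gap_report(
    curated: Sequence[CuratedHaplotype],
    species: Sequence[str] | None = None,
    by_basin: bool = False,
) -> list[tuple]:
    """Deterministic sorted list of (species, life stage[, basin]) cells with
    zero observed haplotypes — the sampling gaps of the registry."""
    pm = presence_matrix(curated, species=species, by_basin=by_basin)
    gaps: list[tuple] = []
    if by_basin:
        for i, sp in enumerate(pm.species):
            for j, b in enumerate(pm.basins):
                for k, st in enumerate(pm.life_stages):
                    if pm.counts[i, j, k] == 0:
                        gaps.append((sp, st, b))
    else:
        for i, sp in enumerate(pm.species):
            for k, st in enumerate(pm.life_stages):
                if pm.counts[i, k] == 0:
                    gaps.append((sp, st))
    return sorted(gaps)


# ---------------------------------------------------------------------------
# registry I/O: FASTA + delimited metadata table keyed by name
# ---------------------------------------------------------------------------


def read_registry(fasta_path: str | Path, meta_path: str | Path) -> list[RegistryRecord]:
    """Read a registry from FASTA plus a metadata table keyed by ``name``.

    Metadata columns: ``species``, ``author``, ``year``, ``basins`` and
    ``life_stages`` (semicolon-separated lists), ``citation``.
    """
    seqs = {r.name: r for r in read_fasta(fasta_path)}
    meta = pd.read_csv(meta_path, sep=None, engine="python", dtype={"name": str})
    if "name" not in meta.columns:
        raise ValidationError(f"{meta_path}: metadata table requires a 'name' column")
    records = []
    for _, row in meta.iterrows():
        name = row["name"]
        if name not in seqs:
            raise ValidationError(f"{meta_path}: no sequence for metadata entry {name!r}")
        year = row.get("year")
        records.append(RegistryRecord(
            name=name,
            sequence=seqs[name].sequence,
            species=row["species"],
            author=str(row.get("author", "") or ""),
            year=None if pd.isna(year) else int(year),
            basins=tuple(str(row.get("basins", "") or "").split(";")) if row.get("basins") else (),
            life_stages=tuple(str(row.get("life_stages", "") or "").split(";"))
            if row.get("life_stages") else (),
            citation=str(row.get("citation", "") or ""),
        ))
    missing = set(seqs) - {r.name for r in records}
    if missing:
        raise ValidationError(f"sequences without metadata: {sorted(missing)}")
    return records


def write_registry(
    curated: Iterable[CuratedHaplotype], fasta_path: str | Path, meta_path: str | Path
) -> None:
    curated = list(curated)
    write_fasta(
        [HaplotypeRecord(name=c.name, sequence=c.sequence, species=c.species) for c in curated],
        fasta_path,
    )
    pd.DataFrame([
        {
            "name": c.name,
            "species": c.species,
            "synonyms": ";".join(c.synonyms),
            "basins": ";".join(c.basins),
            "life_stages": ";".join(c.life_stages),
            "citation": "|".join(c.citations),
        }
        for c in curated
    ]).to_csv(meta_path, index=False)
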