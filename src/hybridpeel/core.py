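"""Shared domain types, file formats and run configuration.

The package operates on a pedigreed population: a sorted pedigree (parents
before progeny), a genetic map of biallelic variants on cM coordinates,
nested marker panels (LD within HD within sequence), per-individual marker
genotypes, and per-individual allele read counts from sequencing.  All
matrices are aligned to pedigree order on the row axis and map order on the
column axis.  Files are plain TSV dialects; indices are 0-based in memory
and ids are used in files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("hybridpeel")

#: sentinel for an unknown parent (index form)
UNKNOWN = -1
#: accepted file spellings for an unknown parent
UNKNOWN_TOKENS = {"0", ".", "NA", ""}
#: genotyping statuses
STATUSES = ("none", "LD", "HD")
MISSING_GENOTYPE = -1


class PedigreeError(ValueError):
    """Raised for structural pedigree defects (duplicate ids, cycles)."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

class Pedigree:
    """Sorted pedigree: every parent precedes its progeny.

    Parameters
    ----------
    ids : sequence of str
        Unique individual identifiers, in sorted order.
    sire, dam : int arrays
        Index of each individual's sire/dam in ``ids``; ``UNKNOWN`` (-1)
        when the parent is not recorded.
    sex : int array, optional
        0 unknown, 1 male, 2 female.  Inferred from parental usage when
        not given.
    generation : int array, optional
        Discrete generation index when known (simulated pedigrees).
    """

    def __init__(self, ids, sire, dam, sex=None, generation=None):
        self.ids = list(ids)
        self.n = len(self.ids)
        self.sire = np.asarray(sire, dtype=np.int64)
        self.dam = np.asarray(dam, dtype=np.int64)
        if len(set(self.ids)) != self.n:
            raise PedigreeError("duplicate individual ids in pedigree")
        if self.sire.shape != (self.n,) or self.dam.shape != (self.n,):
            raise PedigreeError("parent arrays must match id count")
        for name, arr in (("sire", self.sire), ("dam", self.dam)):
            bad = (arr >= np.arange(self.n)) & (arr != UNKNOWN)
            if bad.any():
                raise PedigreeError(
                    f"{name} of {self.ids[int(np.where(bad)[0][0])]} does not "
                    "precede its progeny; pedigree not sorted"
                )
        self.index = {iid: k for k, iid in enumerate(self.ids)}
        if sex is None:
            sex = np.zeros(self.n, dtype=np.int8)
            sex[self.sire[self.sire != UNKNOWN]] = 1
            sex[self.dam[self.dam != UNKNOWN]] = 2
        self.sex = np.asarray(sex, dtype=np.int8)
        self.generation = (
            None if generation is None else np.asarray(generation, dtype=np.int64)
        )

    # -- structure helpers -------------------------------------------------
    @property
    def founders(self) -> np.ndarray:
        """Boolean mask of individuals with both parents unknown."""
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def progeny_of(self) -> list[list[int]]:
        """Children index lists, parallel to ``ids``."""
        out: list[list[int]] = [[] for _ in range(self.n)]
        for child in range(self.n):
            for par in (self.sire[child], self.dam[child]):
                if par != UNKNOWN:
                    out[par].append(child)
        return out

    def parents_of(self, i: int) -> list[int]:
        return [p for p in (int(self.sire[i]), int(self.dam[i])) if p != UNKNOWN]

    def grandparents_of(self, i: int) -> list[int]:
        return [g for p in self.parents_of(i) for g in self.parents_of(p)]

    def relative_position(self) -> np.ndarray:
        """Fractional position in the sorted pedigree (proxy for generation)."""
        if self.n == 1:
            return np.zeros(1)
        return np.arange(self.n) / (self.n - 1)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "Pedigree":
        """Build from (id, sire-id, dam-id[, sex]) tuples.

        Records are topologically re-sorted if parents appear after
        progeny; parents referenced but never defined are auto-created as
        founders with a warning.  Cycles raise :class:`PedigreeError`.
        """
        recs = [tuple(r) for r in records]
        ids = [r[0] for r in recs]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate individual ids in pedigree file")
        defined = set(ids)
        sire_id = {r[0]: _parent_token(r[1]) for r in recs}
        dam_id = {r[0]: _parent_token(r[2]) for r in recs}
        sex_in = {r[0]: int(r[3]) for r in recs if len(r) > 3 and r[3] is not None}
        undefined = []
        for m in (sire_id, dam_id):
            for pid in m.values():
                if pid is not None and pid not in defined:
                    undefined.append(pid)
                    defined.add(pid)
        if undefined:
            warnings.warn(
                f"{len(undefined)} parents referenced but never defined; "
                "created founder records for them",
                stacklevel=2,
            )
            for pid in undefined:
                sire_id[pid] = None
                dam_id[pid] = None
            ids = undefined + ids
        order = _toposort(ids, sire_id, dam_id)
        if order != list(range(len(ids))):
            warnings.warn("pedigree not sorted parents-first; re-sorted", stacklevel=2)
        sorted_ids = [ids[k] for k in order]
        pos = {iid: k for k, iid in enumerate(sorted_ids)}
        sire = np.array(
            [pos[sire_id[i]] if sire_id[i] is not None else UNKNOWN for i in sorted_ids]
        )
        dam = np.array(
            [pos[dam_id[i]] if dam_id[i] is not None else UNKNOWN for i in sorted_ids]
        )
        sex = None
        if sex_in:
            sex = np.array([sex_in.get(i, 0) for i in sorted_ids], dtype=np.int8)
        ped = cls(sorted_ids, sire, dam, sex=sex)
        ped.original_order = ids
        return ped


def _parent_token(tok) -> str | None:
    if tok is None:
        return None
    tok = str(tok).strip()
    return None if tok in UNKNOWN_TOKENS else tok


def _toposort(ids, sire_id, dam_id) -> list[int]:
    """Kahn topological order (parents first), stable on input order."""
    pos = {iid: k for k, iid in enumerate(ids)}
    children: dict[str, list[str]] = {i: [] for i in ids}
    indeg = {i: 0 for i in ids}
    for i in ids:
        for p in (sire_id.get(i), dam_id.get(i)):
            if p is not None:
                children[p].append(i)
                indeg[i] += 1
    ready = sorted([i for i in ids if indeg[i] == 0], key=pos.__getitem__)
    out: list[str] = []
    import heapq

    heap = [pos[i] for i in ready]
    heapq.heapify(heap)
    while heap:
        k = heapq.heappop(heap)
        i = ids[k]
        out.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, pos[c])
    if len(out) != len(ids):
        raise PedigreeError("cyclic ancestry detected in pedigree")
    return [pos[i] for i in out]


def read_pedigree(path) -> Pedigree:
    """Read a pedigree TSV with header ``id sire dam [sex]``."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    for c in ("id", "sire", "dam"):
        if c not in cols:
            raise PedigreeError(f"pedigree file missing column '{c}'")
    recs = []
    for row in df.itertuples(index=False):
        sex = getattr(row, "sex", None)
        recs.append((row.id, row.sire, row.dam, int(sex) if sex not in (None, "") else None))
    return Pedigree.from_records(recs)


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\tsex\n")
        for k, iid in enumerate(ped.ids):
            s = ped.ids[ped.sire[k]] if ped.sire[k] != UNKNOWN else "0"
            d = ped.ids[ped.dam[k]] if ped.dam[k] != UNKNOWN else "0"
            fh.write(f"{iid}\t{s}\t{d}\t{int(ped.sex[k])}\n")


# ---------------------------------------------------------------------------
# Genetic map and panels
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Variant coordinates in centimorgans, ordered within chromosome.

    ``chrom`` and ``pos_cm`` are parallel arrays over all variants, in file
    order (chromosomes contiguous, positions strictly increasing within a
    chromosome).
    """

    chrom: np.ndarray
    pos_cm: np.ndarray
    variant_ids: list[str]

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        self.variant_ids = list(self.variant_ids)
        for c in self.chromosomes:
            p = self.pos_cm[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def chromosomes(self) -> list:
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slice(self, c) -> np.ndarray:
        """Indices of variants on chromosome ``c``."""
        return np.flatnonzero(self.chrom == c)

    def recomb_fractions(self, idx: np.ndarray) -> np.ndarray:
        """Haldane recombination fractions between adjacent variants in ``idx``.

        All variants in ``idx`` must lie on one chromosome.
        """
        if len(set(self.chrom[idx])) > 1:
            raise ValueError("recombination fractions span chromosomes")
        d = np.diff(self.pos_cm[idx]) / 100.0  # Morgans
        return haldane(d)


def haldane(d_morgans):
    """Map distance (Morgans) -> recombination fraction, r = (1-exp(-2d))/2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=float)))


@dataclass
class PanelSet:
    """Nested marker panels as boolean masks over the map's variants."""

    hd_mask: np.ndarray
    ld_mask: np.ndarray

    def __post_init__(self):
        self.hd_mask = np.asarray(self.hd_mask, bool)
        self.ld_mask = np.asarray(self.ld_mask, bool)
        if np.any(self.ld_mask & ~self.hd_mask):
            raise ValueError("LD panel not nested within HD panel")

    def mask_for(self, status: str) -> np.ndarray:
        if status == "HD":
            return self.hd_mask
        if status == "LD":
            return self.ld_mask
        return np.zeros_like(self.hd_mask)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Marker-array genotypes: alt-allele counts 0/1/2, -1 missing."""

    values: np.ndarray  # int8, individuals x variants
    status: np.ndarray  # per-individual genotyping status, dtype '<U4'

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        self.status = np.asarray(self.status)
        ok = np.isin(self.values, [-1, 0, 1, 2])
        if not ok.all():
            raise ValueError("genotypes must be 0, 1, 2 or missing")
        for s in self.status:
            if s not in STATUSES:
                raise ValueError(f"unknown genotyping status {s!r}")

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values.copy(), self.status.copy())


@dataclass
class ReadCounts:
    """Sequencing evidence: per-individual, per-variant ref/alt read tallies."""

    ref: np.ndarray  # int32, individuals x variants
    alt: np.ndarray
    coverage: np.ndarray  # nominal per-individual coverage (x)

    def __post_init__(self):
        self.ref = np.asarray(self.ref, dtype=np.int32)
        self.alt = np.asarray(self.alt, dtype=np.int32)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("negative read count")

    @property
    def total(self) -> np.ndarray:
        return self.ref + self.alt

    def copy(self) -> "ReadCounts":
        return ReadCounts(self.ref.copy(), self.alt.copy(), self.coverage.copy())


@dataclass
class DosageMatrix:
    """Expected alt-allele dosages in [0, 2]."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.nanmin(self.values, initial=0.0) < -1e-9 or np.nanmax(
            self.values, initial=0.0
        ) > 2.0 + 1e-9:
            raise ValueError("dosage outside [0, 2]")


# ---------------------------------------------------------------------------
# File formats (TSV dialects)
# ---------------------------------------------------------------------------

def write_genotypes(gm: GenotypeMatrix, ids: Sequence[str], variant_ids: Sequence[str], path):
    df = pd.DataFrame(gm.values, index=list(ids), columns=list(variant_ids))
    df = df.astype(object).mask(df == MISSING_GENOTYPE, "NA")
    df.insert(0, "status", gm.status)
    df.to_csv(path, sep="\t", index_label="id")


def read_genotypes(path) -> tuple[GenotypeMatrix, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    status = df.pop("status").to_numpy()
    vals = df.to_numpy()
    out = np.full(vals.shape, MISSING_GENOTYPE, dtype=np.int8)
    legal = {"0": 0, "1": 1, "2": 2, "NA": MISSING_GENOTYPE}
    for tok, code in legal.items():
        out[vals == tok] = code
    bad = ~np.isin(vals, list(legal))
    if bad.any():
        raise ValueError(f"illegal genotype token {vals[bad][0]!r}")
    return GenotypeMatrix(out, status), list(df.index), list(df.columns)


def write_reads(rc: ReadCounts, ids: Sequence[str], variant_ids: Sequence[str], path):
    """Long-format read counts; only nonzero (ref+alt) cells are written."""
    ii, vv = np.nonzero(rc.total)
    with open(path, "w") as fh:
        fh.write("id\tvariant\trefReads\taltReads\n")
        for i, v in zip(ii, vv):
            fh.write(f"{ids[i]}\t{variant_ids[v]}\t{rc.ref[i, v]}\t{rc.alt[i, v]}\n")
        fh.write("#coverage\t" + "\t".join(f"{i}={c:g}" for i, c in zip(ids, rc.coverage)) + "\n")


def read_reads(path, ids: Sequence[str], variant_ids: Sequence[str]) -> ReadCounts:
    iidx = {i: k for k, i in enumerate(ids)}
    vidx = {v: k for k, v in enumerate(variant_ids)}
    ref = np.zeros((len(ids), len(variant_ids)), dtype=np.int32)
    alt = np.zeros_like(ref)
    coverage = np.zeros(len(ids))
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id"):
            raise ValueError("read-count file missing header")
        for line in fh:
            if line.startswith("#coverage"):
                for tok in line.rstrip("\n").split("\t")[1:]:
                    iid, c = tok.rsplit("=", 1)
                    coverage[iidx[iid]] = float(c)
                continue
            iid, vid, r, a = line.split()
            r, a = int(r), int(a)
            if r < 0 or a < 0:
                raise ValueError("negative read count in file")
            ref[iidx[iid], vidx[vid]] = r
            alt[iidx[iid], vidx[vid]] = a
    return ReadCounts(ref, alt, coverage)


def write_dosages(dm: DosageMatrix, ids, variant_ids, path):
    df = pd.DataFrame(dm.values, index=list(ids), columns=list(variant_ids))
    df.to_csv(path, sep="\t", index_label="id", float_format="%.6g")


def read_dosages(path) -> tuple[DosageMatrix, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DosageMatrix(df.to_numpy(float)), list(df.index), [str(c) for c in df.columns]


def write_map(gmap: GeneticMap, path):
    with open(path, "w") as fh:
        fh.write("chrom\tvariant\tcM\n")
        for c, v, p in zip(gmap.chrom, gmap.variant_ids, gmap.pos_cm):
            fh.write(f"{c}\t{v}\t{p:.6f}\n")


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "variant": str})
    return GeneticMap(df["chrom"].to_numpy(), df["cM"].to_numpy(float), list(df["variant"]))


def read_matrix(path, kind: str, ids=None, variant_ids=None):
    """Dispatching reader for the three matrix dialects."""
    if kind == "genotypes":
        return read_genotypes(path)
    if kind == "reads":
        return read_reads(path, ids, variant_ids)
    if kind == "dosages":
        return read_dosages(path)
    raise ValueError(f"unknown matrix kind {kind!r}")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline settings (desk-scale defaults).

    The genome is ``n_chromosomes`` x ``chrom_length_cm`` with
    ``variants_per_chromosome`` sequence variants per chromosome and nested
    HD/LD panels.  The sequencing budget defaults to the cost of sequencing
    2% of the population at 2x, split 30/15/25/30 between top sires, top
    dams, focal individuals and the low-coverage top-up.
    """

    # genome
    n_chromosomes: int = 2
    chrom_length_cm: float = 100.0
    variants_per_chromosome: int = 5000
    hd_per_chromosome: int = 200
    ld_per_chromosome: int = 40
    # population
    n_founders: int = 40
    n_generations: int = 10
    litter_mean: float = 6.0
    sire_fraction: float = 0.05
    dam_fraction: float = 0.5
    population_size: int | None = 2000  # stop growing once reached
    founder_beta: tuple[float, float] = (0.3, 0.3)
    # genotyping status fractions (none, LD, HD) by generation band; the
    # early band emulates pedigrees that predate marker-array adoption
    status_early: tuple[float, float, float] = (0.5, 0.0, 0.5)
    status_late: tuple[float, float, float] = (0.02, 0.68, 0.30)
    early_generations: int = 2
    # sequencing
    budget_fraction: float = 0.02
    budget_base_coverage: float = 2.0
    split_fractions: tuple[float, float, float, float] = (0.30, 0.15, 0.25, 0.30)
    coverage_menu: tuple[float, ...] = (1, 2, 5, 15, 30)
    gamma_shape: float = 4.0
    seq_error: float = 0.001
    # peeling
    peel_max_iter: int = 20
    peel_tol: float = 1e-4
    geno_error: float = 1e-4
    seed: int = 2020

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("sequencing split fractions must sum to 1")
        if not (0 < self.seq_error <= 0.1):
            raise ValueError("sequencing error must be in (0, 0.1]")
        for f in ("n_chromosomes", "variants_per_chromosome", "hd_per_chromosome",
                  "ld_per_chromosome", "n_founders", "n_generations"):
            if getattr(self, f) < 0 or (f != "n_generations" and getattr(self, f) <= 0):
                raise ValueError(f"{f} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("split_fractions", "coverage_menu", "founder_beta",
                    "status_early", "status_late"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        blob = repr(sorted(dataclasses.asdict(self).items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def setup_logging(level=logging.INFO, logfile: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
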