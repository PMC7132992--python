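"""Pedigree and data quality control from Mendelian inconsistencies.

A parent-progeny pair that shares marker data is scored by its percentage
of opposing homozygotes (one of the pair 0 and the other 2 at the same
locus), which is impossible without error.  Three repair rules are applied,
in order:

1. an individual whose data conflicts with *all* of its available parents
   and progeny has its marker-array and sequence data removed (suggests the
   sample belongs to someone else);
2. a conflict confined to a single parent-progeny pair cuts that pedigree
   link (both keep their data);
3. a full-sib litter that conflicts with one listed parent while everyone
   involved is compatible elsewhere has that parent replaced by a dummy
   parent without data, preserving the full-sib relationship.

Conflicts are recomputed once after the repairs.  A pair is called
conflicting when its opposing-homozygote percentage exceeds a threshold
(default 2%) over at least ``min_comparable`` loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import UNKNOWN, GenotypeMatrix, Pedigree, ReadCounts

DEFAULT_THRESHOLD = 2.0  # percent opposing homozygotes
MIN_COMPARABLE = 50


@dataclass
class ConflictReport:
    """Per-pair opposing-homozygote statistics and per-individual flags."""

    pairs: pd.DataFrame  # parent, progeny, comparable, opposing, percentage, conflict
    threshold: float
    min_comparable: int

    def conflicting_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["conflict"]]

    def pair_count(self, iid: str) -> tuple[int, int]:
        """(number of scored pairs involving iid, number conflicting)."""
        sel = (self.pairs["parent"] == iid) | (self.pairs["progeny"] == iid)
        sub = self.pairs[sel]
        return len(sub), int(sub["conflict"].sum())


def mendelian_conflicts(genotypes: GenotypeMatrix, ped: Pedigree,
                        threshold: float = DEFAULT_THRESHOLD,
                        min_comparable: int = MIN_COMPARABLE) -> ConflictReport:
    """Score every parent-progeny pair with data on a shared panel."""
    rows = []
    g = genotypes.values
    for child in range(ped.n):
        for par in (ped.sire[child], ped.dam[child]):
            if par == UNKNOWN:
                continue
            gp, gc = g[par], g[child]
            both = (gp >= 0) & (gc >= 0)
            comparable = int(both.sum())
            if comparable == 0:
                continue
            opposing = int((((gp == 0) & (gc == 2)) | ((gp == 2) & (gc == 0)))[both].sum())
            pct = 100.0 * opposing / comparable
            rows.append((ped.ids[par], ped.ids[child], comparable, opposing, pct,
                         pct > threshold and comparable >= min_comparable))
    pairs = pd.DataFrame(rows, columns=["parent", "progeny", "comparable",
                                        "opposing", "percentage", "conflict"])
    return ConflictReport(pairs, threshold, min_comparable)


def _litters(ped: Pedigree) -> dict[tuple[int, int], list[int]]:
    out: dict[tuple[int, int], list[int]] = {}
    for child in range(ped.n):
        if ped.sire[child] != UNKNOWN and ped.dam[child] != UNKNOWN:
            out.setdefault((int(ped.sire[child]), int(ped.dam[child])), []).append(child)
    return out


def apply_qc_rules(ped: Pedigree, genotypes: GenotypeMatrix, reads: ReadCounts | None,
                   threshold: float = DEFAULT_THRESHOLD,
                   min_comparable: int = MIN_COMPARABLE):
    """Apply repair rules 1-3 and recompute conflicts once.

    Returns ``(pedigree, genotypes, reads, action_log)``; inputs are not
    modified.  Dummy parents introduced by rule 3 get reserved ids DUM<N>
    and are prepended as founders, so matrix rows gain leading all-missing
    rows for them.
    """
    report = mendelian_conflicts(genotypes, ped, threshold, min_comparable)
    conf = report.conflicting_pairs()
    genotypes = genotypes.copy()
    reads = reads.copy() if reads is not None else None
    sire = ped.sire.copy()
    dam = ped.dam.copy()
    actions: list[tuple[str, str, str]] = []

    n_conf: dict[str, int] = {}
    n_pairs: dict[str, int] = {}
    for row in report.pairs.itertuples(index=False):
        for iid in (row.parent, row.progeny):
            n_pairs[iid] = n_pairs.get(iid, 0) + 1
            if row.conflict:
                n_conf[iid] = n_conf.get(iid, 0) + 1

    # rule 1: individuals conflicting with everyone they can be compared to
    removed: set[str] = set()
    for iid, nc in n_conf.items():
        if nc == n_pairs[iid] and nc > 0:
            removed.add(iid)
            k = ped.index[iid]
            genotypes.values[k] = -1
            genotypes.status[k] = "none"
            if reads is not None:
                reads.ref[k] = 0
                reads.alt[k] = 0
                reads.coverage[k] = 0.0
            actions.append(("remove_data", iid, "conflicts with all parents and progeny"))

    def alive(row) -> bool:
        return row.parent not in removed and row.progeny not in removed

    # rule 2: conflicts confined to exactly one pair on both sides
    cut: set[tuple[str, str]] = set()
    for row in conf.itertuples(index=False):
        if not alive(row):
            continue
        if n_conf.get(row.parent, 0) == 1 and n_conf.get(row.progeny, 0) == 1:
            child = ped.index[row.progeny]
            par = ped.index[row.parent]
            if sire[child] == par:
                sire[child] = UNKNOWN
            if dam[child] == par:
                dam[child] = UNKNOWN
            cut.add((row.parent, row.progeny))
            actions.append(("cut_link", f"{row.parent}->{row.progeny}",
                            "conflict confined to one pair"))

    # rule 3: a full-sib litter against one parent, compatible elsewhere
    litters = _litters(ped)
    dummy_count = 0
    dummy_rows: list[str] = []
    for (s, d), kids in litters.items():
        if len(kids) < 2:
            continue
        for par, arr in ((s, sire), (d, dam)):
            pid = ped.ids[par]
            if pid in removed:
                continue
            kid_ids = [ped.ids[k] for k in kids]
            pair_conf = {
                (row.parent, row.progeny)
                for row in conf.itertuples(index=False)
                if row.parent == pid and row.progeny in kid_ids and alive(row)
                and (row.parent, row.progeny) not in cut
            }
            if len(pair_conf) != len(kids) or len(kids) == 0:
                continue
            # parent compatible outside the litter, kids compatible elsewhere
            if n_conf.get(pid, 0) != len(kids):
                continue
            if any(n_conf.get(k, 0) != 1 for k in kid_ids):
                continue
            dummy_count += 1
            dummy_id = f"DUM{dummy_count}"
            dummy_rows.append(dummy_id)
            for k in kids:
                if arr is sire:
                    sire[k] = -100 - (dummy_count - 1)  # placeholder, remapped below
                else:
                    dam[k] = -100 - (dummy_count - 1)
            actions.append(("dummy_parent", f"{pid}=>{dummy_id}",
                            f"litter of {len(kids)} conflicts with this parent only"))

    # rebuild pedigree with dummies prepended as founders
    nd = len(dummy_rows)
    ids = dummy_rows + list(ped.ids)
    def remap(v):
        if v == UNKNOWN:
            return UNKNOWN
        if v <= -100:
            return -100 - v  # dummy index (prepended)
        return v + nd
    new_sire = np.array([UNKNOWN] * nd + [remap(v) for v in sire])
    new_dam = np.array([UNKNOWN] * nd + [remap(v) for v in dam])
    sex = np.concatenate([np.zeros(nd, dtype=np.int8), ped.sex])
    gen = None
    if ped.generation is not None:
        gen = np.concatenate([np.zeros(nd, dtype=np.int64), ped.generation])
    new_ped = Pedigree(ids, new_sire, new_dam, sex=sex, generation=gen)
    if nd:
        pad_g = np.full((nd, genotypes.values.shape[1]), -1, dtype=np.int8)
        genotypes = GenotypeMatrix(np.vstack([pad_g, genotypes.values]),
                                   np.concatenate([np.array(["none"] * nd), genotypes.status]))
        if reads is not None:
            pad_r = np.zeros((nd, reads.ref.shape[1]), dtype=np.int32)
            reads = ReadCounts(np.vstack([pad_r, reads.ref]),
                               np.vstack([pad_r, reads.alt]),
                               np.concatenate([np.zeros(nd), reads.coverage]))

    log = pd.DataFrame(actions, columns=["action", "subject", "reason"])
    final = mendelian_conflicts(genotypes, new_ped, threshold, min_comparable)
    return new_ped, genotypes, reads, log, final


def depth_filter(reads: ReadCounts, factor: float = 3.0) -> np.ndarray:
    """Mask of variants whose mean depth exceeds ``factor`` times the
    average realized depth (indicative of repetitive regions).

    Depth is averaged over sequenced individuals (nominal coverage > 0).
    """
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    seq = reads.coverage > 0
    if not seq.any():
        raise ValueError("no sequenced individuals")
    depth = reads.total[seq].mean(axis=0)
    return depth > factor * depth.mean()
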