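"""Three-tier allocation of a fixed sequencing budget across a pedigree.

The strategy mirrors common practice for building sequence resources in
breeding populations: (1) sires and dams with the most genotyped progeny
are sequenced broadly but shallowly (2x and 1x), (2) a few "focal" key
ancestors whose haplotypes reach the largest share of the population are
sequenced deeply (15-30x, with their parents at 5x), and (3) the remainder
of the budget is spread at 1x over individuals whose recent ancestors carry
little cumulative coverage.  Focal individuals are chosen by a greedy
pedigree-descendant coverage rule: each pick maximizes the number of
descendants not already covered by an earlier pick (a pedigree proxy for
haplotype representation; no phased haplotypes are required).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import UNKNOWN, Pedigree

DEFAULT_FRACTIONS = (0.30, 0.15, 0.25, 0.30)
DEFAULT_MENU = (1.0, 2.0, 5.0, 15.0, 30.0)


@dataclass
class BudgetPlan:
    """Coverage assignment produced by :func:`build_plan`."""

    total_budget: float
    fractions: tuple[float, float, float, float]
    coverage_menu: tuple[float, ...]
    assignment: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("budget fractions must sum to 1")

    @property
    def assigned(self) -> float:
        return float(sum(self.assignment.values()))

    def histogram(self) -> pd.DataFrame:
        """Coverage histogram in the shape of a per-population summary row."""
        cov = np.array(list(self.assignment.values()), dtype=float)
        return pd.DataFrame(
            {
                "individuals_sequenced": [len(cov)],
                "n_1x": [int((cov == 1).sum())],
                "n_2x": [int((cov == 2).sum())],
                "n_5x": [int((cov == 5).sum())],
                "n_15_30x": [int((cov >= 15).sum())],
                "total_coverage": [float(cov.sum())],
            }
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tcoverage\n")
            for iid, c in self.assignment.items():
                fh.write(f"{iid}\t{c:g}\n")


def rank_top_parents(ped: Pedigree, genotyped: set[str]) -> tuple[list[str], list[str]]:
    """Rank sires and dams by number of genotyped progeny (descending).

    Ties are broken by earlier pedigree position, then id.  Parents with no
    genotyped progeny are omitted.
    """
    sire_counts: dict[int, int] = {}
    dam_counts: dict[int, int] = {}
    for child in range(ped.n):
        if ped.ids[child] not in genotyped:
            continue
        if ped.sire[child] != UNKNOWN:
            s = int(ped.sire[child])
            sire_counts[s] = sire_counts.get(s, 0) + 1
        if ped.dam[child] != UNKNOWN:
            d = int(ped.dam[child])
            dam_counts[d] = dam_counts.get(d, 0) + 1
    key = lambda counts: sorted(counts, key=lambda i: (-counts[i], i, ped.ids[i]))
    return [ped.ids[i] for i in key(sire_counts)], [ped.ids[i] for i in key(dam_counts)]


def _descendant_sets(ped: Pedigree) -> list[np.ndarray]:
    """Boolean descendant masks per individual (excluding the individual)."""
    desc = [np.zeros(ped.n, dtype=bool) for _ in range(ped.n)]
    for child in range(ped.n - 1, -1, -1):
        for par in (ped.sire[child], ped.dam[child]):
            if par != UNKNOWN:
                desc[par][child] = True
                desc[par] |= desc[child]
    return desc


def select_focal(ped: Pedigree, budget_slice: float,
                 already: dict[str, float] | None = None,
                 high: float = 15.0, first: float = 30.0,
                 parent_cov: float = 5.0) -> dict[str, float]:
    """Greedy focal-individual selection by uncovered-descendant count.

    Each pick is the individual with the most pedigree descendants not yet
    covered by any earlier pick; the first pick is sequenced at ``first``
    (30x), later picks at ``high`` (15x), and the not-yet-sequenced parents
    of each pick at ``parent_cov`` (5x), while the slice lasts.
    """
    assignment: dict[str, float] = {}
    if budget_slice <= 0:
        return assignment
    taken = dict(already or {})
    desc = _descendant_sets(ped)
    covered = np.zeros(ped.n, dtype=bool)
    remaining = budget_slice
    first_pick = True
    while True:
        cov_needed = first if first_pick else high
        if remaining < min(high, cov_needed):
            break
        cov = min(cov_needed, first if remaining >= first and first_pick else high)
        gains = [
            (int((desc[i] & ~covered).sum()), i)
            for i in range(ped.n)
            if ped.ids[i] not in taken and ped.ids[i] not in assignment
        ]
        if not gains:
            break
        best_gain, best = max(gains, key=lambda t: (t[0], -t[1]))
        if best_gain == 0:
            break
        assignment[ped.ids[best]] = cov
        remaining -= cov
        covered |= desc[best]
        covered[best] = True
        first_pick = False
        for par in (ped.sire[best], ped.dam[best]):
            if par == UNKNOWN:
                continue
            pid = ped.ids[par]
            if pid in taken or pid in assignment or remaining < parent_cov:
                continue
            assignment[pid] = parent_cov
            remaining -= parent_cov
    return assignment


def _ancestor_coverage(ped: Pedigree, current: dict[str, float], i: int,
                       depth: int = 2) -> float:
    """Cumulative assigned coverage over ancestors within ``depth`` generations."""
    total = 0.0
    frontier = [i]
    for _ in range(depth):
        nxt = []
        for j in frontier:
            for par in (ped.sire[j], ped.dam[j]):
                if par != UNKNOWN:
                    nxt.append(int(par))
        for par in nxt:
            total += current.get(ped.ids[par], 0.0)
        frontier = nxt
    return total


def topup_undersequenced(ped: Pedigree, current: dict[str, float],
                         budget_slice: float, threshold: float = 10.0) -> dict[str, float]:
    """Spread 1x units over unsequenced individuals with deficient ancestry.

    Eligible individuals are unsequenced and have cumulative assigned
    coverage over their parents and grandparents below ``threshold`` (10x);
    the most deficient are served first.
    """
    out: dict[str, float] = {}
    units = int(budget_slice)  # 1x units
    if units <= 0:
        return out
    cand = []
    for i in range(ped.n):
        if current.get(ped.ids[i], 0.0) > 0:
            continue
        cum = _ancestor_coverage(ped, current, i)
        if cum < threshold:
            cand.append((cum, i))
    cand.sort(key=lambda t: (t[0], t[1]))
    for _, i in cand[:units]:
        out[ped.ids[i]] = 1.0
    return out


def build_plan(ped: Pedigree, genotyped: set[str], total_budget: float,
               fractions: tuple[float, float, float, float] = DEFAULT_FRACTIONS,
               coverage_menu: tuple[float, ...] = DEFAULT_MENU) -> BudgetPlan:
    """Compose the three allocation steps under one global budget.

    Steps draw from a single remaining-budget pool with per-step targets
    given by ``fractions``; unspent capacity rolls forward, and the focal
    step may draw ahead of its nominal share so that at least one deep
    (15-30x) key ancestor is funded whenever the global budget allows.
    """
    if total_budget < 1:
        raise ValueError("budget smaller than one 1x unit")
    plan = BudgetPlan(total_budget, tuple(fractions), tuple(coverage_menu))
    assignment = plan.assignment
    remaining = float(total_budget)
    sires, dams = rank_top_parents(ped, genotyped)
    # step 1: top sires at 2x, top dams at 1x
    spent = 0.0
    slice1 = fractions[0] * total_budget
    for s in sires:
        if spent >= slice1 or remaining < 2 or s in assignment:
            break
        assignment[s] = 2.0
        spent += 2.0
        remaining -= 2.0
    spent = 0.0
    slice2 = fractions[1] * total_budget
    for d in dams:
        if spent >= slice2 or remaining < 1 or d in assignment:
            break
        assignment[d] = 1.0
        spent += 1.0
        remaining -= 1.0
    # step 2: focal individuals; allow the tier to reach one deep pick even
    # if its nominal share alone cannot afford it
    if fractions[2] > 0:
        slice3 = max(fractions[2] * total_budget, min(30.0, remaining))
        focal = select_focal(ped, min(slice3, remaining), already=assignment)
        for iid, c in focal.items():
            assignment[iid] = c
            remaining -= c
    # step 3: 1x top-up of under-sequenced ancestry (all that remains)
    if fractions[3] > 0:
        topup = topup_undersequenced(ped, assignment, remaining)
        for iid, c in topup.items():
            assignment[iid] = c
            remaining -= c
    assert plan.assigned <= total_budget + 1.0 + 1e-9
    return plan
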