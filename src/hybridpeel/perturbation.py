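"""Error-injection stress tests: data misassignment and pedigree errors.

Each scenario corrupts the data of one high-coverage target individual in
a worst-case way — its sequence reads replaced by another high-coverage
individual's, its marker-array record replaced by an HD-genotyped
individual's, or another high-coverage individual's progeny re-assigned to
it — the population is re-imputed, and the damage is measured as the
dosage correlation between the clean-data and corrupted-data runs, for the
target and for each class of relatives.  A removal-control (deleting the
target's reads, as in leave-one-out validation) bounds the information
loss without corruption.  Replacement is one-directional: the donor keeps
its own data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import UNKNOWN, Pedigree
from .evaluation import maf_corrected_correlation
from .peeling import PeelSettings, hybrid_peel
from .synthetic_data import Dataset

SCENARIO_TYPES = ("seq-misassign", "array-misassign", "pedigree-misassign",
                  "removal-control")
RELATIVE_CLASSES = ("ind", "gpar", "par", "prog", "gprog",
                    "misass_prog", "misass_gprog")


@dataclass
class PerturbationScenario:
    type: str
    target_id: str
    donor_id: str | None = None
    reassigned_progeny: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.type not in SCENARIO_TYPES:
            raise ValueError(f"unknown scenario type {self.type}")
        if self.donor_id is not None and self.donor_id == self.target_id:
            raise ValueError("donor must differ from target")


def eligible_donors(dataset: Dataset, scenario_type: str, target_id: str) -> list[str]:
    """Donor pool per scenario type.

    seq: individuals sequenced at high coverage (>= 15x); array:
    HD-genotyped individuals; pedigree: high-coverage individuals with
    progeny positioned after the target (so the pedigree stays sorted).
    """
    ped = dataset.pedigree
    t = ped.index[target_id]
    if scenario_type == "removal-control":
        return []
    if scenario_type == "array-misassign":
        pool = [ped.ids[i] for i in np.flatnonzero(dataset.genotypes.status == "HD")]
    else:
        pool = [ped.ids[i] for i in np.flatnonzero(dataset.reads.coverage >= 15)]
    if scenario_type == "pedigree-misassign":
        prog = dataset.pedigree.progeny_of()
        pool = [p for p in pool
                if any(c > t for c in prog[ped.index[p]])]
    return [p for p in pool if p != target_id]


def make_scenario(dataset: Dataset, scenario_type: str, target_id: str,
                  rng) -> PerturbationScenario:
    """Draw a random eligible donor (and progeny for pedigree errors)."""
    rng = np.random.default_rng(rng)
    if scenario_type == "removal-control":
        return PerturbationScenario(scenario_type, target_id)
    pool = eligible_donors(dataset, scenario_type, target_id)
    if not pool:
        raise ValueError(f"no eligible donors for {scenario_type} on {target_id}")
    donor = pool[int(rng.integers(len(pool)))]
    reassigned: list[str] = []
    if scenario_type == "pedigree-misassign":
        ped = dataset.pedigree
        t = ped.index[target_id]
        prog = ped.progeny_of()[ped.index[donor]]
        reassigned = [ped.ids[c] for c in prog if c > t]
    return PerturbationScenario(scenario_type, target_id, donor, reassigned)


def inject(dataset: Dataset, scenario: PerturbationScenario) -> Dataset:
    """Apply exactly the scenario's stated modification to a copied dataset."""
    out = dataset.copy_observations()
    ped = dataset.pedigree
    t = ped.index[scenario.target_id]
    if scenario.type == "removal-control":
        out.reads.ref[t] = 0
        out.reads.alt[t] = 0
        out.reads.coverage[t] = 0.0
        return out
    d = ped.index[scenario.donor_id]
    if scenario.type == "seq-misassign":
        out.reads.ref[t] = dataset.reads.ref[d]
        out.reads.alt[t] = dataset.reads.alt[d]
        out.reads.coverage[t] = dataset.reads.coverage[d]
        return out
    if scenario.type == "array-misassign":
        out.genotypes.values[t] = dataset.genotypes.values[d]
        out.genotypes.status[t] = dataset.genotypes.status[d]
        return out
    # pedigree-misassign: donor's progeny now list the target as parent
    sire = ped.sire.copy()
    dam = ped.dam.copy()
    for cid in scenario.reassigned_progeny:
        c = ped.index[cid]
        if sire[c] == d:
            sire[c] = t
        if dam[c] == d:
            dam[c] = t
    out.pedigree = Pedigree(list(ped.ids), sire, dam, sex=ped.sex.copy(),
                            generation=None if ped.generation is None
                            else ped.generation.copy())
    return out


def impact(reference_dosages: np.ndarray, perturbed_dosages: np.ndarray,
           ped: Pedigree, target_id: str,
           misassigned_progeny: list[str] | None = None) -> dict[str, float]:
    """Mean within-class dosage correlation between clean and corrupted runs.

    Correlations are MAF-corrected (both runs centered by twice the
    reference run's population allele frequency), the same statistic used
    for imputation accuracy; without the correction the correlation
    between any two members of a closed nucleus population is inflated
    towards 1 by the shared allele-frequency profile.  Classes: the target
    itself, its grandparents, parents, progeny and grandprogeny (true
    relatives exclude any misassigned progeny), and the misassigned
    progeny/grandprogeny for pedigree errors.  Empty classes are NaN.
    """
    freqs = reference_dosages.mean(axis=0) / 2.0
    t = ped.index[target_id]
    prog = ped.progeny_of()
    mis = [ped.index[i] for i in (misassigned_progeny or [])]
    mis_g = [g for m in mis for g in prog[m]]
    groups = {
        "ind": [t],
        "gpar": ped.grandparents_of(t),
        "par": ped.parents_of(t),
        "prog": [c for c in prog[t] if c not in mis],
        "gprog": [g for c in prog[t] if c not in mis for g in prog[c]],
        "misass_prog": mis,
        "misass_gprog": mis_g,
    }
    out = {}
    for name, members in groups.items():
        if not members:
            out[name] = float("nan")
            continue
        vals = [maf_corrected_correlation(reference_dosages[m],
                                          perturbed_dosages[m], freqs)
                for m in set(members)]
        vals = [v for v in vals if not np.isnan(v)]
        out[name] = float(np.mean(vals)) if vals else float("nan")
    return out


def run_test3(dataset: Dataset, validation_ids: list[str], seed: int = 0,
              settings: PeelSettings | None = None,
              variant_idx: np.ndarray | None = None,
              reference_dosages: np.ndarray | None = None,
              scenario_types: tuple[str, ...] = SCENARIO_TYPES) -> pd.DataFrame:
    """Inject every scenario type for every validation target and re-impute.

    Returns one row per (type, target) with the per-class correlations
    against the clean-data reference run.
    """
    rng = np.random.default_rng(seed)
    if variant_idx is None:
        variant_idx = np.arange(dataset.gmap.n_variants)
    if reference_dosages is None:
        ref, _ = hybrid_peel(dataset.pedigree, dataset.genotypes, dataset.reads,
                             dataset.gmap, dataset.panels, settings,
                             variants=variant_idx)
        reference_dosages = ref.values
    rows = []
    for stype in scenario_types:
        for target in validation_ids:
            scen = make_scenario(dataset, stype, target, rng)
            pert = inject(dataset, scen)
            dos, _ = hybrid_peel(pert.pedigree, pert.genotypes, pert.reads,
                                 pert.gmap, pert.panels, settings,
                                 variants=variant_idx)
            res = impact(reference_dosages, dos.values, dataset.pedigree, target,
                         scen.reassigned_progeny)
            rows.append({"type": stype, "target": target, "donor": scen.donor_id,
                         **res})
    return pd.DataFrame(rows)


def summarize_test3(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and dispersion per scenario type and relative class."""
    rows = []
    for stype, grp in results.groupby("type"):
        for cls in RELATIVE_CLASSES:
            vals = grp[cls].dropna()
            rows.append({"type": stype, "class": cls, "n": len(vals),
                         "mean": vals.mean() if len(vals) else float("nan"),
                         "sd": vals.std() if len(vals) > 1 else float("nan")})
    return pd.DataFrame(rows)
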