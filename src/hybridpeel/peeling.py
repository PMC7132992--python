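"""Two-step hybrid peeling: genotype calling, phasing and imputation on a
pedigree from marker-array genotypes and low-coverage sequence reads.

Genotypes are carried as probability 4-vectors over *ordered* genotypes
(aa, aA, Aa, AA), the first symbol being the paternal allele.  Inheritance
at a locus is described by a segregation state (pp, pm, mp, mm): whether the
paternal gamete copied the sire's paternal (p) or maternal (m) haplotype,
and likewise for the maternal gamete within the dam.

The engine is sum-product message passing on the family factor graph of the
pedigree.  Each nuclear family (sire, dam, children) is one factor that
multiplies the children's segregation-conditioned transmission kernels; an
individual's posterior factorizes into anterior information (the message
from its parents' family), its own data likelihood (penetrance), and one
posterior term per family in which it is a parent.  On loop-free pedigrees
the schedule (a parents-first sweep followed by a progeny-first sweep,
iterated to tolerance) is exact; with inbreeding loops it is iterative
(loopy) peeling and an accepted approximation.

Hybrid peeling runs multi-locus iterative peeling on the marker panel only
— jointly estimating genotype and segregation posteriors with a
forward-backward pass along each chromosome — then transfers the
segregation posteriors to every sequence variant by per-indicator Markov
bridging between flanking panel loci, and finishes with fast single-locus
peeling at every variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    UNKNOWN,
    DosageMatrix,
    GeneticMap,
    GenotypeMatrix,
    PanelSet,
    Pedigree,
    ReadCounts,
    haldane,
)

FLOOR = 1e-30

#: ordered-genotype helper: paternal/maternal allele of state g
_PAT = np.array([0, 0, 1, 1])
_MAT = np.array([0, 1, 0, 1])


def _build_kernel() -> np.ndarray:
    """K[s, g_sire, g_dam, g_child]: transmission indicator per seg state.

    Under state s the child's paternal allele copies the sire's paternal
    haplotype if the first index of s is p, else the sire's maternal one;
    symmetrically for the dam.
    """
    K = np.zeros((4, 4, 4, 4))
    for s in range(4):
        use_sire_mat = s >> 1  # 1 when paternal gamete copied sire's maternal hap
        use_dam_mat = s & 1
        for gs in range(4):
            pat = _MAT[gs] if use_sire_mat else _PAT[gs]
            for gd in range(4):
                mat = _MAT[gd] if use_dam_mat else _PAT[gd]
                K[s, gs, gd, 2 * pat + mat] = 1.0
    return K


KERNEL = _build_kernel()


@dataclass
class PeelSettings:
    """Numerical settings for the peeling engine."""

    max_iter: int = 20
    tol: float = 1e-4
    geno_error: float = 1e-4  # marker-array observation error
    seq_error: float = 1e-3  # per-read sequencing error
    damping: float = 0.0  # optional message damping for loopy pedigrees
    chunk_size: int = 600  # variants peeled per single-locus batch

    def __post_init__(self):
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tolerance must be positive and iterations >= 1")


def _norm(x: np.ndarray) -> np.ndarray:
    x = np.maximum(x, FLOOR)
    return x / x.sum(axis=-1, keepdims=True)


def hw_prior(p: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg ordered-genotype prior, shape (..., 4)."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return np.stack([q * q, q * p, p * q, p * p], axis=-1)


# ---------------------------------------------------------------------------
# Penetrance
# ---------------------------------------------------------------------------

def penetrance(genotypes: GenotypeMatrix | None, reads: ReadCounts | None,
               settings: PeelSettings, variant_idx: np.ndarray | None = None) -> np.ndarray:
    """Likelihood of the observed data given each ordered genotype.

    Read counts contribute a binomial term with alt-read probability
    (e, 1/2, 1/2, 1-e) for (aa, aA, Aa, AA); an observed array genotype
    contributes 1 - eps to the matching ordered states and eps/2 to the
    rest.  Cells with no data are all-ones.  Returns (n, L, 4), unnormalized.
    """
    if genotypes is None and reads is None:
        raise ValueError("need at least one of genotypes or reads")
    src = genotypes.values if genotypes is not None else reads.ref
    n, L = src.shape
    cols = np.arange(L) if variant_idx is None else np.asarray(variant_idx)
    pen = np.ones((n, len(cols), 4))
    if reads is not None:
        ref = reads.ref[:, cols].astype(float)
        alt = reads.alt[:, cols].astype(float)
        e = settings.seq_error
        p_alt = np.array([e, 0.5, 0.5, 1.0 - e])
        lp = np.log(p_alt)
        lq = lp[::-1]  # 1 - p_alt[g] = p_alt[3-g]; reuse for exact ref/alt symmetry
        has = (ref + alt) > 0
        for g in range(4):
            pen[..., g][has] = np.exp(alt[has] * lp[g] + ref[has] * lq[g])
    if genotypes is not None:
        eps = settings.geno_error
        W = np.full((3, 4), eps / 2.0)
        W[0, 0] = W[1, 1] = W[1, 2] = W[2, 3] = 1.0 - eps
        gv = genotypes.values[:, cols]
        obs = gv >= 0
        pen[obs] *= W[gv[obs]]
    return pen


def estimate_alt_freqs(genotypes: GenotypeMatrix | None, reads: ReadCounts | None,
                       n_individuals: int) -> np.ndarray:
    """Per-variant alt-allele frequency from array and read evidence.

    The estimate is (sum of alt evidence) / (sum of evidence): observed
    genotypes contribute g/2 each, covered sites contribute their alt-read
    fraction.  Variants with no evidence fall back to 0.5; everything is
    clipped away from fixation by 1/(2N).
    """
    num = den = None
    if genotypes is not None:
        obs = genotypes.values >= 0
        num = np.where(obs, genotypes.values / 2.0, 0.0).sum(axis=0)
        den = obs.sum(axis=0).astype(float)
    if reads is not None:
        tot = reads.total
        has = tot > 0
        # 0.5 + (alt-ref)/2n == alt/n, written so ref/alt relabelling negates
        # the deviation exactly in floating point
        frac = np.where(has, 0.5 + (reads.alt - reads.ref) / (2.0 * np.maximum(tot, 1)), 0.0)
        num = frac.sum(axis=0) + (num if num is not None else 0.0)
        den = has.sum(axis=0) + (den if den is not None else 0.0)
    p = np.full(num.shape, 0.5)
    nz = den > 0
    p[nz] = num[nz] / den[nz]
    lo = 1.0 / (2 * n_individuals)
    return np.clip(p, lo, 1.0 - lo)


# ---------------------------------------------------------------------------
# Pedigree peeling structure
# ---------------------------------------------------------------------------

class _PedStructure:
    """Families and membership maps, with virtual co-parents for children
    that have exactly one recorded parent."""

    def __init__(self, ped: Pedigree):
        self.n = ped.n
        sire = ped.sire.astype(np.int64).copy()
        dam = ped.dam.astype(np.int64).copy()
        n_eff = ped.n
        for i in range(ped.n):
            if (sire[i] == UNKNOWN) != (dam[i] == UNKNOWN):
                if sire[i] == UNKNOWN:
                    sire[i] = n_eff
                else:
                    dam[i] = n_eff
                n_eff += 1
        self.n_eff = n_eff
        self.is_founder = np.zeros(n_eff, dtype=bool)
        self.is_founder[: ped.n] = (sire == UNKNOWN) & (dam == UNKNOWN)
        self.is_founder[ped.n:] = True
        fams: dict[tuple[int, int], list[int]] = {}
        for i in range(ped.n):
            if sire[i] != UNKNOWN:
                fams.setdefault((int(sire[i]), int(dam[i])), []).append(i)
        ordered = sorted(fams.items(), key=lambda kv: min(kv[1]))
        self.families = [(s, d, np.array(ch)) for (s, d), ch in ordered]
        self.child_fam = np.full(n_eff, -1, dtype=np.int64)
        self.child_slot = np.zeros(n_eff, dtype=np.int64)
        self.parent_fams: list[list[tuple[int, str]]] = [[] for _ in range(n_eff)]
        for f, (s, d, ch) in enumerate(self.families):
            self.parent_fams[s].append((f, "s"))
            self.parent_fams[d].append((f, "d"))
            for k, c in enumerate(ch):
                self.child_fam[c] = f
                self.child_slot[c] = k


class PeelEngine:
    """Message-passing engine over one batch of loci.

    Parameters
    ----------
    struct : _PedStructure
    pen : (n, L, 4) penetrance for the real individuals
    seg : (n, L, 4) segregation probabilities used in the transmission
        kernel of each child (uniform = no linkage information)
    prior_p : (L,) founder alt-allele frequencies
    """

    def __init__(self, struct: _PedStructure, pen: np.ndarray, seg: np.ndarray,
                 prior_p: np.ndarray, settings: PeelSettings):
        self.st = struct
        self.settings = settings
        n_eff, L = struct.n_eff, pen.shape[1]
        self.L = L
        self.pen = np.ones((n_eff, L, 4))
        self.pen[: struct.n] = np.maximum(pen, FLOOR)
        self.seg = np.full((n_eff, L, 4), 0.25)
        self.seg[: struct.n] = seg
        self.prior = hw_prior(prior_p)  # (L, 4)
        flat = np.full((L, 4), 0.25)
        self.to_s = [flat.copy() for _ in struct.families]
        self.to_d = [flat.copy() for _ in struct.families]
        self.to_c = [np.full((len(ch), L, 4), 0.25) for _, _, ch in struct.families]
        self.belief = self._all_beliefs()

    # -- message assembly --------------------------------------------------
    def _msg_to_family(self, i: int, f_excl: int) -> np.ndarray:
        """Belief of i excluding the message incoming from family f_excl."""
        st = self.st
        out = self.pen[i].copy()
        if st.is_founder[i]:
            out = out * self.prior
        cf = st.child_fam[i]
        if cf >= 0 and cf != f_excl:
            out = out * self.to_c[cf][st.child_slot[i]]
        for f, role in st.parent_fams[i]:
            if f == f_excl:
                continue
            out = out * (self.to_s[f] if role == "s" else self.to_d[f])
        return _norm(out)

    def _family_terms(self, f: int):
        """Parent messages, per-child kernels folded with child messages."""
        s, d, ch = self.st.families[f]
        fs = self._msg_to_family(s, f)
        fd = self._msg_to_family(d, f)
        h = np.empty((len(ch), self.L, 4, 4))
        fc = np.empty((len(ch), self.L, 4))
        for k, c in enumerate(ch):
            fc[k] = self._msg_to_family(c, f)
            h[k] = np.einsum("ls,sabc,lc->lab", self.seg[c], KERNEL, fc[k],
                             optimize=True)
        return fs, fd, fc, h

    @staticmethod
    def _loo_products(h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Leave-one-out and full products over the child axis."""
        nc = h.shape[0]
        pre = np.ones_like(h)
        suf = np.ones_like(h)
        for k in range(1, nc):
            pre[k] = pre[k - 1] * h[k - 1]
        for k in range(nc - 2, -1, -1):
            suf[k] = suf[k + 1] * h[k + 1]
        return pre * suf, (pre[-1] * h[-1] if nc else None)

    def _update(self, msg_list, f_or_k, new, lam):
        old = msg_list[f_or_k]
        msg_list[f_or_k] = _norm(lam * old + (1 - lam) * new) if lam else new

    # -- sweeps ------------------------------------------------------------
    def sweep(self) -> None:
        """One parents-first pass (children messages) then progeny-first
        pass (parent messages)."""
        lam = self.settings.damping
        for f, (s, d, ch) in enumerate(self.st.families):
            fs, fd, fc, h = self._family_terms(f)
            W = fs[:, :, None] * fd[:, None, :]
            loo, _ = self._loo_products(h)
            for k, c in enumerate(ch):
                tc = np.einsum("lab,ls,sabc->lc", W * loo[k], self.seg[c], KERNEL,
                               optimize=True)
                self._update(self.to_c[f], k, _norm(tc), lam)
        for f in range(len(self.st.families) - 1, -1, -1):
            s, d, ch = self.st.families[f]
            fs, fd, fc, h = self._family_terms(f)
            _, Hall = self._loo_products(h)
            self._update(self.to_s, f, _norm(np.einsum("lb,lab->la", fd, Hall)), lam)
            self._update(self.to_d, f, _norm(np.einsum("la,lab->lb", fs, Hall)), lam)

    def _all_beliefs(self) -> np.ndarray:
        b = np.empty((self.st.n, self.L, 4))
        for i in range(self.st.n):
            b[i] = self._msg_to_family(i, -2)  # exclude nothing
        return b

    def run(self) -> np.ndarray:
        """Iterate sweeps until the posterior change falls under tolerance."""
        for _ in range(self.settings.max_iter):
            self.sweep()
            new = self._all_beliefs()
            delta = np.abs(new - self.belief).max()
            self.belief = new
            if delta < self.settings.tol:
                break
        return self.belief

    # -- segregation emissions --------------------------------------------
    def seg_emissions(self) -> np.ndarray:
        """Per-individual, per-locus likelihood of each segregation state.

        For child c with parents' within-family messages and sibling terms,
        E_c(s) = sum_{g_s,g_d,g_c} m_s(g_s) m_d(g_d) [sib products]
        K[s](g_s,g_d,g_c) m_c(g_c).  Founders get flat emissions.
        """
        E = np.ones((self.st.n_eff, self.L, 4))
        for f, (s, d, ch) in enumerate(self.st.families):
            fs, fd, fc, h = self._family_terms(f)
            W = fs[:, :, None] * fd[:, None, :]
            loo, _ = self._loo_products(h)
            for k, c in enumerate(ch):
                E[c] = np.einsum("lab,sabc,lc->ls", W * loo[k], KERNEL, fc[k],
                                 optimize=True)
        return _norm(E)


# ---------------------------------------------------------------------------
# Single-locus peeling
# ---------------------------------------------------------------------------

def peel_genotypes(ped: Pedigree, pen: np.ndarray, seg: np.ndarray,
                   prior_p: np.ndarray, settings: PeelSettings | None = None,
                   struct: _PedStructure | None = None) -> np.ndarray:
    """Segregation-aware single-locus iterative peeling over a batch of loci.

    Returns normalized ordered-genotype posteriors, shape (n, L, 4).
    """
    settings = settings or PeelSettings()
    struct = struct or _PedStructure(ped)
    engine = PeelEngine(struct, pen, seg, np.asarray(prior_p, float), settings)
    return engine.run()


def single_locus_peel(ped: Pedigree, pen_locus: np.ndarray, seg_locus: np.ndarray,
                      prior_freq: float, settings: PeelSettings | None = None) -> np.ndarray:
    """Peel one locus: pen and seg are (n, 4); returns (n, 4) posteriors."""
    post = peel_genotypes(ped, pen_locus[:, None, :], seg_locus[:, None, :],
                          np.array([prior_freq]), settings)
    return post[:, 0, :]


def dosages_from_probabilities(probs: np.ndarray) -> np.ndarray:
    """Expected alt dosage P(aA) + P(Aa) + 2 P(AA)."""
    return probs[..., 1] + probs[..., 2] + 2.0 * probs[..., 3]


# ---------------------------------------------------------------------------
# Multi-locus peeling (segregation estimation)
# ---------------------------------------------------------------------------

def _transition_matrices(r: np.ndarray) -> np.ndarray:
    """Per-interval 4x4 segregation transitions: independent indicator
    switches with probability r each (paternal x maternal Kronecker)."""
    if np.any(r >= 0.5) or np.any(r < 0):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    stay = 1.0 - r
    R = np.empty((len(r), 2, 2))
    R[:, 0, 0] = R[:, 1, 1] = stay
    R[:, 0, 1] = R[:, 1, 0] = r
    return np.einsum("kab,kcd->kacbd", R, R).reshape(len(r), 4, 4)


def _forward_backward(E: np.ndarray, M: np.ndarray) -> np.ndarray:
    """HMM smoothing for many individuals at once.

    E: (m, L, 4) emissions; M: (L-1, 4, 4) transitions.  Uniform initial
    distribution; returns normalized posteriors (m, L, 4).
    """
    m, L, _ = E.shape
    f = np.empty_like(E)
    f[:, 0] = _norm(E[:, 0] * 0.25)
    for k in range(1, L):
        f[:, k] = _norm((f[:, k - 1] @ M[k - 1]) * E[:, k])
    b = np.ones((m, 4))
    post = np.empty_like(E)
    post[:, L - 1] = _norm(f[:, L - 1])
    for k in range(L - 2, -1, -1):
        b = _norm((E[:, k + 1] * b) @ M[k].T)
        post[:, k] = _norm(f[:, k] * b)
    return post


def multi_locus_peel(ped: Pedigree, pen: np.ndarray, gmap: GeneticMap,
                     panel_idx: np.ndarray, settings: PeelSettings | None = None,
                     struct: _PedStructure | None = None,
                     prior_p: np.ndarray | None = None,
                     return_genotype_probs: bool = False):
    """Estimate segregation probabilities on ordered panel loci.

    Alternates genotype peeling (with the current segregation estimates)
    and a forward-backward smoothing of each individual's segregation
    indicators along every chromosome, until the segregation posteriors
    stabilize.  Founders keep the uniform distribution.
    """
    settings = settings or PeelSettings()
    struct = struct or _PedStructure(ped)
    panel_idx = np.asarray(panel_idx)
    L = len(panel_idx)
    blocks = []  # (slice into panel axis, transition matrices)
    for c in gmap.chromosomes:
        on_c = np.flatnonzero(np.isin(panel_idx, gmap.chrom_slice(c)))
        if len(on_c) == 0:
            continue
        if np.any(np.diff(panel_idx[on_c]) <= 0):
            raise ValueError("panel loci must be ordered by map position")
        r = gmap.recomb_fractions(panel_idx[on_c])
        blocks.append((on_c, _transition_matrices(r)))
    if prior_p is None:
        prior_p = np.full(L, 0.5)
    seg = np.full((struct.n, L, 4), 0.25)
    engine = PeelEngine(struct, pen, seg, np.asarray(prior_p, float), settings)
    nonf = np.flatnonzero(~struct.is_founder[: struct.n])
    for _ in range(settings.max_iter):
        engine.sweep()
        E = engine.seg_emissions()[: struct.n]
        new_seg = np.full_like(seg, 0.25)
        for on_c, M in blocks:
            new_seg[np.ix_(nonf, on_c)] = _forward_backward(E[np.ix_(nonf, on_c)], M)
        delta = np.abs(new_seg - seg).max()
        seg = new_seg
        engine.seg[: struct.n] = seg
        if delta < max(settings.tol, 1e-3):
            break
    if return_genotype_probs:
        return seg, engine._all_beliefs()
    return seg


# ---------------------------------------------------------------------------
# Segregation interpolation
# ---------------------------------------------------------------------------

def interpolate_segregation(seg_panel: np.ndarray, gmap: GeneticMap,
                            panel_idx: np.ndarray, target_idx: np.ndarray) -> np.ndarray:
    """Transfer panel segregation posteriors to arbitrary variants.

    Each segregation indicator (paternal, maternal) is bridged
    independently: its marginal at each flanking panel locus is propagated
    to the target through a two-state Markov chain with the Haldane
    recombination fraction for the intervening distance, and the two
    flanking forecasts are combined as independent sources (product of the
    per-state weights, renormalized).  Beyond terminal panel loci only one
    flank contributes, which decays toward the uniform distribution.
    Targets that coincide with a panel locus receive that locus's posterior
    unchanged.
    """
    panel_idx = np.asarray(panel_idx)
    target_idx = np.asarray(target_idx)
    n = seg_panel.shape[0]
    out = np.full((n, len(target_idx), 4), 0.25)
    sig_p = seg_panel[..., 0] + seg_panel[..., 1]  # P(paternal gamete = p)
    sig_m = seg_panel[..., 0] + seg_panel[..., 2]
    exact = {v: k for k, v in enumerate(panel_idx)}
    for c in gmap.chromosomes:
        cvars = gmap.chrom_slice(c)
        p_on = np.flatnonzero(np.isin(panel_idx, cvars))
        t_on = np.flatnonzero(np.isin(target_idx, cvars))
        if len(t_on) == 0:
            continue
        if len(p_on) == 0:
            raise ValueError(f"no panel loci on chromosome {c}")
        ppos = gmap.pos_cm[panel_idx[p_on]]
        tpos = gmap.pos_cm[target_idx[t_on]]
        right = np.searchsorted(ppos, tpos)
        left = right - 1
        sigs = np.empty((n, len(t_on), 2))
        for which, sig in enumerate((sig_p, sig_m)):
            w1 = np.ones((n, len(t_on)))
            w0 = np.ones((n, len(t_on)))
            for flank, valid in ((left, left >= 0), (right, right < len(ppos))):
                if not valid.any():
                    continue
                fl = flank[valid]
                r = haldane(np.abs(tpos[valid] - ppos[fl]) / 100.0)
                q = sig[:, p_on[fl]] * (1 - r) + (1 - sig[:, p_on[fl]]) * r
                w1[:, valid] *= q
                w0[:, valid] *= 1 - q
            sigs[..., which] = w1 / (w1 + w0)
        out[:, t_on, 0] = sigs[..., 0] * sigs[..., 1]
        out[:, t_on, 1] = sigs[..., 0] * (1 - sigs[..., 1])
        out[:, t_on, 2] = (1 - sigs[..., 0]) * sigs[..., 1]
        out[:, t_on, 3] = (1 - sigs[..., 0]) * (1 - sigs[..., 1])
    for k, v in enumerate(target_idx):
        if v in exact:
            out[:, k, :] = seg_panel[:, exact[v], :]
    return out


# ---------------------------------------------------------------------------
# Hybrid peeling
# ---------------------------------------------------------------------------

def hybrid_peel(ped: Pedigree, genotypes: GenotypeMatrix | None, reads: ReadCounts | None,
                gmap: GeneticMap, panels: PanelSet,
                settings: PeelSettings | None = None,
                variants: np.ndarray | None = None,
                return_probabilities: bool = False):
    """Impute expected allele dosages at every variant.

    Step 1: multi-locus iterative peeling on the HD panel loci using all
    marker-array data as observed (LD individuals contribute their LD loci
    directly; they are not pre-imputed to HD) plus the panel-site reads.
    Step 2: the segregation posteriors are bridged to every variant and
    fast single-locus peeling is run per variant, with founder priors set
    to allele frequencies estimated from the data.

    ``variants`` restricts the single-locus step to a subset of map
    indices (the multi-locus step always uses the full panel); the output
    columns then follow that subset's order.

    Returns ``(DosageMatrix, probs)`` where ``probs`` is the (n, L, 4)
    float32 ordered-genotype posterior array when requested, else None.
    """
    settings = settings or PeelSettings()
    struct = _PedStructure(ped)
    n = ped.n
    panel_idx = np.flatnonzero(panels.hd_mask)
    freqs = estimate_alt_freqs(genotypes, reads, n)
    pen_panel = penetrance(genotypes, reads, settings, variant_idx=panel_idx)
    seg_panel = multi_locus_peel(ped, pen_panel, gmap, panel_idx, settings,
                                 struct=struct, prior_p=freqs[panel_idx])
    targets = np.arange(gmap.n_variants) if variants is None else np.asarray(variants)
    out_col = {v: k for k, v in enumerate(targets)}
    dosages = np.empty((n, len(targets)))
    probs = np.empty((n, len(targets), 4), dtype=np.float32) if return_probabilities else None
    for c in gmap.chromosomes:
        cvars = targets[np.isin(targets, gmap.chrom_slice(c))]
        for start in range(0, len(cvars), settings.chunk_size):
            idx = cvars[start: start + settings.chunk_size]
            if len(idx) == 0:
                continue
            seg = interpolate_segregation(seg_panel, gmap, panel_idx, idx)
            pen = penetrance(genotypes, reads, settings, variant_idx=idx)
            post = peel_genotypes(ped, pen, seg, freqs[idx], settings, struct=struct)
            cols = [out_col[v] for v in idx]
            dosages[:, cols] = dosages_from_probabilities(post)
            if probs is not None:
                probs[:, cols, :] = post.astype(np.float32)
    return DosageMatrix(np.clip(dosages, 0.0, 2.0)), probs
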