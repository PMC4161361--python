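"""Conditional genotype moments given flanking markers (Haley-Knott regressors).

At a putative locus between markers the genotype indicator x is unobserved.
Following Haley-Knott regression it is replaced by its conditional expectation
d = E[x | flanking markers]; the conditional variance c = Var[x | flanking
markers] is retained because it drives the per-individual over-dispersion
psi_i = 1 + sum_j b_j^2 c_ij used by the iteratively reweighted fit.

Probabilities come from a no-interference (Haldane) Markov model along the
chromosome.  Conditioning uses the nearest informative marker on each side
only (standard interval-mapping practice, not full multipoint); at chromosome
ends, or next to missing genotypes, a single side or the population prior is
used.  F2 genotypes are treated as two independent gamete chains with the
phase of double heterozygotes summed over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genmap import GeneticMap, LocusGrid, map_distance_to_recomb

__all__ = [
    "RegressorSet",
    "flanking_genotype_probs",
    "indicator_moments",
    "f2_indicator_moments",
    "build_regressors",
]


@dataclass
class RegressorSet:
    """Per-individual, per-locus expected indicators and conditional variances.

    For backcross/DH/RIL designs ``d``/``c`` are the additive-indicator
    moments.  For an F2, ``d``/``c`` hold the additive (+1/0/-1) moments and
    ``d_dom``/``c_dom`` the heterozygote-indicator moments; the model design
    matrix interleaves them via :meth:`design_matrix`.
    """

    grid: LocusGrid
    d: np.ndarray
    c: np.ndarray
    design: str
    coding: tuple = (1.0, -1.0)
    d_dom: np.ndarray | None = None
    c_dom: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.d.shape[0]

    @property
    def n_loci(self) -> int:
        return self.d.shape[1]

    def design_matrix(self) -> np.ndarray:
        """n x K matrix of regressor columns (additive, then dominance)."""
        if self.d_dom is None:
            return self.d
        return np.hstack([self.d, self.d_dom])

    def cond_var_matrix(self) -> np.ndarray:
        """n x K conditional variances aligned with :meth:`design_matrix`."""
        if self.c_dom is None:
            return self.c
        return np.hstack([self.c, self.c_dom])

    def column_locus(self) -> np.ndarray:
        """Grid-locus index of each design column."""
        k = self.n_loci
        if self.d_dom is None:
            return np.arange(k)
        return np.concatenate([np.arange(k), np.arange(k)])

    def column_effect_type(self) -> np.ndarray:
        k = self.n_loci
        if self.d_dom is None:
            return np.array(["additive"] * k, dtype=object)
        return np.array(["additive"] * k + ["dominance"] * k, dtype=object)


def _rstar(r, design):
    """RIL map expansion; backcross/DH/F2 gametes use r unchanged."""
    r = np.asarray(r, dtype=float)
    if design == "RIL":
        r = 2.0 * r / (1.0 + 2.0 * r)
    return r


def flanking_genotype_probs(left_geno, right_geno, r_left, r_right, design="backcross"):
    """Probability vector of the locus genotype given flanking genotypes.

    Two-class designs (backcross/DH/RIL) return ``[P(class +1), P(class -1)]``
    with genotypes coded +1/-1; F2 returns ``[P(QQ), P(Qq), P(qq)]`` with
    genotypes given as allele counts 2/1/0 (or +1/0/-1 additive codes).
    ``None`` on a side means no informative marker there.
    """
    if design == "F2":
        return _f2_cond_probs_scalar(left_geno, right_geno, r_left, r_right)
    rL = float(_rstar(r_left, design)) if left_geno is not None else None
    rR = float(_rstar(r_right, design)) if right_geno is not None else None
    if left_geno is None and right_geno is None:
        return np.array([0.5, 0.5])
    if left_geno is not None and left_geno not in (1, -1):
        raise ValueError(f"invalid two-class genotype code: {left_geno!r}")
    if right_geno is not None and right_geno not in (1, -1):
        raise ValueError(f"invalid two-class genotype code: {right_geno!r}")
    # likelihood of locus class +1 given each side
    pL = 1.0 if left_geno is None else (1.0 - rL if left_geno == 1 else rL)
    qL = 1.0 if left_geno is None else (rL if left_geno == 1 else 1.0 - rL)
    pR = 1.0 if right_geno is None else (1.0 - rR if right_geno == 1 else rR)
    qR = 1.0 if right_geno is None else (rR if right_geno == 1 else 1.0 - rR)
    num = pL * pR
    den = num + qL * qR
    p = num / den
    return np.array([p, 1.0 - p])


def indicator_moments(probs, coding=(1.0, -1.0)):
    """First two central moments of a coded genotype: d = E[x], c = Var[x]."""
    probs = np.asarray(probs, dtype=float)
    codes = np.asarray(coding, dtype=float)
    d = float(probs @ codes)
    c = float(probs @ codes**2 - d**2)
    return d, max(c, 0.0)


def f2_indicator_moments(probs):
    """Additive and dominance moments from a (P(QQ), P(Qq), P(qq)) vector."""
    pQQ, pQq, pqq = (float(p) for p in probs)
    d_add = pQQ - pqq
    c_add = pQQ + pqq - d_add**2
    d_dom = pQq
    c_dom = pQq * (1.0 - pQq)
    return d_add, max(c_add, 0.0), d_dom, max(c_dom, 0.0)


# -- F2 conditional probabilities -----------------------------------------

def _gamete_orderings(count):
    """Ordered allele assignments (per gamete) consistent with an allele count."""
    if count == 0:
        return [(0, 0)]
    if count == 2:
        return [(1, 1)]
    return [(0, 1), (1, 0)]


def _t(a, b, r):
    return 1.0 - r if a == b else r


def _f2_cond_probs_scalar(gL, gR, rL, rR):
    """Genotype distribution at a locus from flanking F2 genotypes.

    ``gL``/``gR`` are allele counts (0/1/2) or additive codes (-1/0/+1);
    ``None`` means missing on that side.  Sums over the phase of heterozygous
    flanks; the two gametes are independent Haldane chains.
    """
    # accept additive codes -1/0/+1 as well as allele counts 0/1/2
    def as_count(g):
        if g is None:
            return None
        g = int(g)
        if g == -1:
            return 0
        if g in (0, 1, 2):
            return g
        raise ValueError(f"invalid F2 genotype code: {g!r}")

    cL, cR = as_count(gL), as_count(gR)
    out = np.zeros(3)
    if cL is None and cR is None:
        return np.array([0.25, 0.5, 0.25])
    ordsL = _gamete_orderings(cL) if cL is not None else [(None, None)]
    ordsR = _gamete_orderings(cR) if cR is not None else [(None, None)]
    for oL in ordsL:
        for oR in ordsR:
            # per-gamete unnormalized distribution over mid allele {0,1}
            u = []
            for g in range(2):
                uu = np.ones(2)
                for h in range(2):
                    if oL[g] is not None:
                        uu[h] *= _t(oL[g], h, rL)
                    if oR[g] is not None:
                        uu[h] *= _t(h, oR[g], rR)
                u.append(uu)
            w = 1.0 / (len(ordsL) * len(ordsR))
            for h1 in range(2):
                for h2 in range(2):
                    out[h1 + h2] += w * u[0][h1] * u[1][h2]
    total = out.sum()
    if total <= 0:  # impossible flank combination (e.g. r = 0 contradiction)
        return np.array([0.25, 0.5, 0.25])
    out /= total
    # out is indexed by allele count; return (P(QQ), P(Qq), P(qq)) with QQ = count 2
    return np.array([out[2], out[1], out[0]])


def _f2_table(rL, rR):
    """3x3 table of genotype distributions indexed by (left count, right count)."""
    tab = np.zeros((3, 3, 3))
    for gL in range(3):
        for gR in range(3):
            tab[gL, gR] = _f2_cond_probs_scalar(gL, gR, rL, rR)
    return tab


# -- vectorized regressor construction -------------------------------------

def _nearest_observed(obs_mask):
    """For each (individual, marker) the nearest observed marker index at or
    before / at or after that marker; -1 where none exists."""
    n, m = obs_mask.shape
    idx = np.arange(m)[None, :].repeat(n, axis=0)
    fwd = np.where(obs_mask, idx, -1)
    fwd = np.maximum.accumulate(fwd, axis=1)
    bwd = np.where(obs_mask, idx, m)
    bwd = np.flip(np.minimum.accumulate(np.flip(bwd, axis=1), axis=1), axis=1)
    bwd[bwd == m] = -1
    return fwd, bwd


def build_regressors(genotypes, gmap: GeneticMap, grid: LocusGrid, design="backcross",
                     coding=(1.0, -1.0)) -> RegressorSet:
    """Expected indicators and conditional variances at every grid locus.

    ``genotypes`` is an n x m matrix aligned with the map's marker order:
    +1/-1 for the two-class designs, allele counts 2/1/0 (or +1/0/-1) for F2,
    NaN for missing.  At a locus coinciding with an observed marker the coded
    genotype is reproduced exactly with zero conditional variance.
    """
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    if m != gmap.n_markers:
        raise ValueError(f"genotype matrix has {m} columns but the map has {gmap.n_markers} markers")
    n_loci = len(grid)
    d = np.zeros((n, n_loci))
    c = np.zeros((n, n_loci))
    is_f2 = design == "F2"
    d_dom = np.zeros((n, n_loci)) if is_f2 else None
    c_dom = np.zeros((n, n_loci)) if is_f2 else None

    code_hi, code_lo = float(coding[0]), float(coding[1])
    starts = np.concatenate([[0], np.cumsum([ch.n_markers for ch in gmap.chromosomes])])
    for ci, chrom in enumerate(gmap.chromosomes):
        cols = slice(starts[ci], starts[ci + 1])
        Gc = G[:, cols]
        if is_f2:
            Gc = np.where(Gc == -1, 0.0, Gc)  # accept additive codes
        obs = np.isfinite(Gc)
        valid_codes = (0.0, 1.0, 2.0) if is_f2 else (1.0, -1.0)
        invalid = obs & ~np.isin(Gc, valid_codes)
        if np.any(invalid):
            bad = np.argwhere(invalid)[0]
            raise ValueError(
                f"invalid genotype code {Gc[tuple(bad)]!r} for individual {bad[0]}, "
                f"marker {chrom.marker_names[bad[1]]}"
            )
        fwd, bwd = _nearest_observed(obs)
        mpos = chrom.marker_pos_cM
        loci = np.flatnonzero(grid.chrom_idx == ci)
        for gl in loci:
            p = grid.pos_cM[gl]
            li, ri = grid.left_idx[gl], grid.right_idx[gl]
            # nearest informative marker at or left of li / at or right of ri
            L = fwd[:, li]
            R = bwd[:, ri]
            dist_L = np.where(L >= 0, p - mpos[np.clip(L, 0, None)], np.nan)
            dist_R = np.where(R >= 0, mpos[np.clip(R, 0, None)] - p, np.nan)
            rL = np.where(L >= 0, _rstar(map_distance_to_recomb(np.nan_to_num(dist_L)), design), np.nan)
            rR = np.where(R >= 0, _rstar(map_distance_to_recomb(np.nan_to_num(dist_R)), design), np.nan)
            gL = np.where(L >= 0, Gc[np.arange(n), np.clip(L, 0, None)], np.nan)
            gR = np.where(R >= 0, Gc[np.arange(n), np.clip(R, 0, None)], np.nan)
            if is_f2:
                _fill_f2_locus(gl, gL, gR, rL, rR, d, c, d_dom, c_dom)
            else:
                _fill_two_class_locus(gl, gL, gR, rL, rR, d, c, code_hi, code_lo)
    return RegressorSet(
        grid=grid, d=d, c=c, design=design, coding=(code_hi, code_lo),
        d_dom=d_dom, c_dom=c_dom,
    )


def _fill_two_class_locus(gl, gL, gR, rL, rR, d, c, code_hi, code_lo):
    """Vectorized backcross/DH/RIL conditional moments at one grid locus."""
    hasL = np.isfinite(gL)
    hasR = np.isfinite(gR)
    pL = np.where(hasL, np.where(gL == 1, 1.0 - rL, rL), 1.0)
    qL = np.where(hasL, np.where(gL == 1, rL, 1.0 - rL), 1.0)
    pR = np.where(hasR, np.where(gR == 1, 1.0 - rR, rR), 1.0)
    qR = np.where(hasR, np.where(gR == 1, rR, 1.0 - rR), 1.0)
    num = np.nan_to_num(pL) * np.nan_to_num(pR)
    den = num + np.nan_to_num(qL) * np.nan_to_num(qR)
    p_hi = np.where(hasL | hasR, num / den, 0.5)
    dj = p_hi * code_hi + (1.0 - p_hi) * code_lo
    cj = p_hi * code_hi**2 + (1.0 - p_hi) * code_lo**2 - dj**2
    d[:, gl] = dj
    c[:, gl] = np.maximum(cj, 0.0)


def _fill_f2_locus(gl, gL, gR, rL, rR, d, c, d_dom, c_dom):
    """F2 conditional moments at one grid locus; groups individuals sharing
    the same flank distances so the 3x3 table is computed once per group."""
    n = gL.size
    hasL = np.isfinite(gL)
    hasR = np.isfinite(gR)
    keyL = np.where(hasL, np.round(rL, 12), -1.0)
    keyR = np.where(hasR, np.round(rR, 12), -1.0)
    keys = np.stack([keyL, keyR], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    for u in range(uniq.shape[0]):
        sel = inverse == u
        krL, krR = uniq[u]
        if krL < 0 and krR < 0:
            probs3 = np.array([0.25, 0.5, 0.25])
            da, ca, dd, cd = f2_indicator_moments(probs3)
            d[sel, gl], c[sel, gl] = da, ca
            d_dom[sel, gl], c_dom[sel, gl] = dd, cd
            continue
        idx = np.flatnonzero(sel)
        if krL >= 0 and krR >= 0:
            tab = _f2_table(krL, krR)
            for i in idx:
                probs3 = tab[int(gL[i]), int(gR[i])]
                da, ca, dd, cd = f2_indicator_moments(probs3)
                d[i, gl], c[i, gl] = da, ca
                d_dom[i, gl], c_dom[i, gl] = dd, cd
        else:
            for i in idx:
                a = int(gL[i]) if krL >= 0 else None
                b = int(gR[i]) if krR >= 0 else None
                probs3 = _f2_cond_probs_scalar(a, b, max(krL, 0.0), max(krR, 0.0))
                da, ca, dd, cd = f2_indicator_moments(probs3)
                d[i, gl], c[i, gl] = da, ca
                d_dom[i, gl], c_dom[i, gl] = dd, cd
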