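"""Compiled inner loop for gamete assembly.

The allele state of a population is stored row-major as ``A[(n, 2k)]``:
row ``i`` holds individual ``i``'s first haplotype in columns ``[0, k)`` and
its second in ``[k, 2k)``. Keeping both haplotypes of a parent in one row
makes the crossover copy loop cache-friendly, which is what lets ensembles
of hundreds of populations run in minutes on one core.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def assemble_gametes(alleles, parents, start_hap, xo_off, xo_pos, out, gsum):
    """Build one generation of gametes with recombination.

    Parameters
    ----------
    alleles : (n, 2k) float array
        Parental allele matrix (row layout, see module docstring).
    parents : (G,) int array
        Parent index for each gamete; gametes ``0..n_pop-1`` become the first
        haplotype of offspring ``0..n_pop-1``, gametes ``n_pop..2*n_pop-1``
        the second.
    start_hap : (G,) int array
        Which parental haplotype (0/1) the copy starts from.
    xo_off, xo_pos : int arrays
        CSR-style crossover layout: gamete ``g`` switches source haplotype
        after locus boundary ``xo_pos[p]`` for ``p`` in
        ``[xo_off[g], xo_off[g+1])``; positions are sorted within a gamete.
        Boundary ``b`` separates loci ``b`` and ``b+1``; an even number of
        crossovers in the same boundary cancels pairwise.
    out : (n_pop, 2k) float array
        Offspring allele matrix, written in place.
    gsum : (G,) float64 array
        Sum of each gamete's allelic values (half the offspring genotype),
        accumulated in double precision.
    """
    n_pop, twok = out.shape
    k = twok // 2
    G = 2 * n_pop
    for g in range(G):
        p = parents[g]
        base = start_hap[g] * k
        if g < n_pop:
            row, col = g, 0
        else:
            row, col = g - n_pop, k
        lo = 0
        for ptr in range(xo_off[g], xo_off[g + 1]):
            hi = xo_pos[ptr] + 1
            for j in range(lo, hi):
                out[row, col + j] = alleles[p, base + j]
            base = k - base
            lo = hi
        for j in range(lo, k):
            out[row, col + j] = alleles[p, base + j]
        s = 0.0
        for j in range(col, col + k):
            s += out[row, j]
        gsum[g] = s
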