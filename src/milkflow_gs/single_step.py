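"""Single-step HBLUP: the multi-trait animal model with H-inverse.

The single-step evaluation re-solves the exact animal model of the
pedigree BLUP after replacing the inverse numerator relationship matrix
by ``H^-1 = A^-1 + [0 0; 0 G_w^-1 - A22^-1]``, where ``G_w`` is the
genomic relationship matrix blended with the pedigree block,
``G_w = w G + (1 - w) A22`` (default w = 0.9).  Phenotypes of
non-genotyped cows and genotypes of the sires therefore enter one set of
equations; variance components are identical to the pedigree run.
"""

from __future__ import annotations

import numpy as np

from .blup import BLUPResults, MultiTraitBLUP
from .data import GenotypeMatrix, Pedigree
from .qc import impute_missing
from .relationship import (
    blend_G,
    build_A,
    build_A_inverse,
    build_G,
    build_H_inverse,
    compute_inbreeding,
    invert_dense,
)
from .traits import TraitParameters


class SingleStepBLUP:
    """Six-trait HBLUP model; ``fit`` mirrors :class:`MultiTraitBLUP`.

    ``genotypes`` may be None or empty, in which case H-inverse reduces to
    A-inverse and the fit equals the pedigree BLUP exactly.
    """

    def __init__(
        self,
        phenotypes,
        pedigree: Pedigree,
        genotypes: GenotypeMatrix | None,
        params: TraitParameters,
        blend_w: float = 0.9,
        G: object | None = None,
    ):
        self.pedigree = pedigree
        self.params = params
        self.blend_w = blend_w
        inb = compute_inbreeding(pedigree)
        a_inv = build_A_inverse(pedigree, inb)
        if genotypes is None or genotypes.n_animals == 0:
            kinv = a_inv
        else:
            genotyped = genotypes.animal_ids
            missing = set(genotyped) - set(pedigree.ids)
            if missing:
                raise ValueError(
                    f"genotyped animals absent from pedigree: {sorted(missing)[:5]}"
                )
            a22 = build_A(pedigree, subset=genotyped)
            if G is None:
                G = build_G(impute_missing(genotypes))
            gw = blend_G(G, a22, blend_w) if blend_w < 1.0 else G
            g_inv = invert_dense(gw, "G_inverse")
            a22_inv = invert_dense(a22, "A22_inverse")
            kinv = build_H_inverse(a_inv, g_inv, a22_inv, genotyped)
        self._model = MultiTraitBLUP(phenotypes, pedigree, params,
                                     relationship_inverse=kinv,
                                     inbreeding=inb)

    def fit(self, **fit_kwargs) -> BLUPResults:
        return self._model.fit(**fit_kwargs)


def fit_hblup(
    phenotypes,
    pedigree: Pedigree,
    genotypes: GenotypeMatrix | None,
    params: TraitParameters,
    blend_w: float = 0.9,
    **fit_kwargs,
) -> BLUPResults:
    """Convenience wrapper building and fitting the single-step model."""
    return SingleStepBLUP(phenotypes, pedigree, genotypes, params,
                          blend_w).fit(**fit_kwargs)
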