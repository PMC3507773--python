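"""Deregression of EBV into pseudo-phenotypes (dEBV) and their weights.

A sire's EBV mixes its own (progeny) information with the parent average.
Deregression solves the implied 2 x 2 mixed-model system in the unknowns
(PA, EBV) backwards: from the reliabilities it reconstructs the effective
information content of the parent average (``Z'Z_PA``) and of the
individual (``Z'Z_i``), forms the right-hand sides, and reads off

* ``dEBV = y_i / Z'Z_i`` — the individual's own information, free of the
  parent average and un-shrunk,
* ``aPA = y_PA / Z'Z_PA`` — the parent-average information component,

with reliabilities ``r2_dEBV = Z'Z_i / (Z'Z_i + lambda)`` and
``r2_aPA = Z'Z_PA / (Z'Z_PA + 4 lambda)``, ``lambda = (1 - h2)/h2``.

Records enter stage-two genomic models weighted by

    w = (1 - h2) / ((c + (1 - r2_dEBV) / r2_dEBV) h2)

where ``c`` (default 0.4) is the fraction of genetic variance not
accounted for by the markers.  Traits are deregressed independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_WEIGHT = 1e6


def _information(r2_i: float, r2_pa: float, h2: float):
    """Effective information contents (Z'Z_PA, Z'Z_i, lambda)."""
    r2_i = np.asarray(r2_i, dtype=float)
    r2_pa = np.asarray(r2_pa, dtype=float)
    if np.any((h2 <= 0) | (h2 >= 1)):
        raise ValueError("h2 must lie strictly in (0, 1)")
    if np.any(r2_pa < 0) or np.any(r2_pa >= 0.5):
        raise ValueError("parent-average reliability must lie in [0, 0.5)")
    if np.any(r2_i >= 1) or np.any(r2_i <= r2_pa):
        raise ValueError(
            "individual reliability must exceed the parent-average "
            "reliability and be below 1 (no own information otherwise)"
        )
    lam = (1.0 - h2) / h2
    alpha = 1.0 / (0.5 - r2_pa)
    delta = (0.5 - r2_pa) / (1.0 - r2_i)
    zz_pa = lam * (0.5 * alpha - 4.0) + 0.5 * lam * np.sqrt(
        alpha**2 + 16.0 / delta
    )
    zz_i = delta * zz_pa + 2.0 * lam * (2.0 * delta - 1.0)
    if np.any(zz_i <= 0):
        raise ValueError("non-positive individual information; reliabilities "
                         "too close for deregression")
    return zz_pa, zz_i, lam


def deregress(ebv_i, r2_i, pa, r2_pa, h2):
    """Deregress one EBV (or arrays of them) for a single trait.

    Returns ``(debv, r2_debv, apa, r2_apa)``.
    """
    zz_pa, zz_i, lam = _information(r2_i, r2_pa, h2)
    pa = np.asarray(pa, dtype=float)
    ebv_i = np.asarray(ebv_i, dtype=float)
    y_pa = (zz_pa + 4.0 * lam) * pa - 2.0 * lam * ebv_i
    y_i = -2.0 * lam * pa + (zz_i + 2.0 * lam) * ebv_i
    debv = y_i / zz_i
    r2_debv = zz_i / (zz_i + lam)
    apa = y_pa / zz_pa
    r2_apa = zz_pa / (zz_pa + 4.0 * lam)
    return debv, r2_debv, apa, r2_apa


def recombine(debv, r2_debv, apa, r2_apa, h2):
    """Selection-index recombination of (aPA, dEBV) back into the EBV.

    Inverse of :func:`deregress`: rebuild the information contents from
    the reliabilities, form the right-hand sides and solve the 2 x 2
    mixed-model system; returns the EBV component.
    """
    lam = (1.0 - h2) / h2
    zz_i = lam * np.asarray(r2_debv) / (1.0 - np.asarray(r2_debv))
    zz_pa = 4.0 * lam * np.asarray(r2_apa) / (1.0 - np.asarray(r2_apa))
    y_pa = zz_pa * np.asarray(apa)
    y_i = zz_i * np.asarray(debv)
    det = (zz_pa + 4.0 * lam) * (zz_i + 2.0 * lam) - 4.0 * lam**2
    ebv = ((zz_pa + 4.0 * lam) * y_i + 2.0 * lam * y_pa) / det
    return ebv


def debv_weight(r2_debv, h2, c: float = 0.4, max_weight: float = MAX_WEIGHT):
    """Record weight for a deregressed proof.

    ``w = (1 - h2) / ((c + (1 - r2)/r2) h2)``; weights are capped at
    ``max_weight`` (the formula diverges as c -> 0, r2 -> 1).
    """
    r2 = np.asarray(r2_debv, dtype=float)
    if np.any(r2 <= 0):
        raise ValueError("dEBV reliability must be positive to form a weight")
    w = (1.0 - h2) / ((c + (1.0 - r2) / r2) * h2)
    return np.minimum(w, max_weight)


@dataclass
class DeregressionResult:
    """Per-sire, per-trait deregressed proofs and companions.

    All frames are indexed by animal id with one column per trait; sires
    whose reliabilities violated the deregression domain for a trait hold
    NaN there and are listed in ``dropped``.
    """

    debv: pd.DataFrame
    r2_debv: pd.DataFrame
    weight: pd.DataFrame
    apa: pd.DataFrame
    r2_apa: pd.DataFrame
    c: float = 0.4
    dropped: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        rows = []
        for t in self.debv.columns:
            rows.append(pd.DataFrame({
                "id": self.debv.index, "trait": t, "debv": self.debv[t],
                "r2_debv": self.r2_debv[t], "weight": self.weight[t],
                "apa": self.apa[t], "r2_apa": self.r2_apa[t],
            }))
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def deregress_results(
    blup_results,
    ids,
    c: float = 0.4,
    on_invalid: str = "raise",
) -> DeregressionResult:
    """Deregress the BLUP proofs of the given animals, all traits.

    ``on_invalid='drop'`` silently NaN-masks animals whose reliabilities
    fall outside the deregression domain for a trait (e.g. no information
    beyond the parent average) instead of raising.
    """
    ids = np.asarray(ids, dtype=object)
    traits = list(blup_results.ebv.columns)
    h2 = blup_results.params.h2
    pa_df, r2pa_df = blup_results.parent_average(ids)
    ebv = blup_results.ebv.loc[ids]
    r2 = blup_results.reliability.loc[ids]

    shape = (len(ids), len(traits))
    out = {k: np.full(shape, np.nan) for k in
           ("debv", "r2_debv", "weight", "apa", "r2_apa")}
    dropped = {}
    for j, t in enumerate(traits):
        r2i = r2[t].to_numpy()
        r2pa = np.minimum(r2pa_df[t].to_numpy(), 0.5 - 1e-9)
        valid = (r2i > r2pa) & (r2i < 1.0) & (r2pa < 0.5) & ~np.isnan(r2i)
        if not valid.all():
            if on_invalid == "raise":
                bad = ids[~valid][:5]
                raise ValueError(
                    f"deregression domain violated for trait {t!r}, "
                    f"e.g. animals {list(bad)}"
                )
            dropped[t] = list(ids[~valid])
        if valid.any():
            debv, r2d, apa, r2apa = deregress(
                ebv[t].to_numpy()[valid], r2i[valid],
                pa_df[t].to_numpy()[valid], r2pa[valid], h2[j],
            )
            out["debv"][valid, j] = debv
            out["r2_debv"][valid, j] = r2d
            out["apa"][valid, j] = apa
            out["r2_apa"][valid, j] = r2apa
            out["weight"][valid, j] = debv_weight(r2d, h2[j], c)
    frames = {k: pd.DataFrame(v, index=ids, columns=traits)
              for k, v in out.items()}
    return DeregressionResult(c=c, dropped=dropped, **frames)
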