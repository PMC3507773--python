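"""Pedigree, genomic and single-step relationship matrices.

* ``compute_inbreeding`` — Wright's inbreeding coefficients by memoised
  kinship recursion (equivalent to the tabular-method diagonal minus one).
* ``build_A`` — numerator relationship matrix by the tabular method; a
  subset (e.g. A22 among genotyped animals) is extracted against the full
  pedigree via sparse solves with A-inverse, so no full dense A is formed.
* ``build_A_inverse`` — Henderson's rules with inbreeding accounted for.
* ``build_G`` — VanRaden genomic relationship matrix
  ``G = Z Z' / (2 sum p_i (1 - p_i))`` with SNP columns centred by twice
  the allele frequency.
* ``blend_G`` — ``w G + (1 - w) A22`` (guarantees invertibility for w < 1).
* ``build_H_inverse`` — the single-step matrix
  ``H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]`` on the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import GenotypeMatrix, Pedigree


@dataclass
class RelationshipMatrix:
    """A (possibly sparse) symmetric relationship structure over animals."""

    kind: str  # A, A_inverse, A22, A22_inverse, G, G_blended, G_inverse, H_inverse
    ids: np.ndarray
    values: object  # dense ndarray or scipy sparse matrix
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape inconsistent with ids")
        self._index = {a: i for i, a in enumerate(self.ids)}

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)

    def index_of(self, animal_ids) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in animal_ids], dtype=np.int64)
        except KeyError as err:
            raise KeyError(f"animal {err.args[0]!r} not in matrix") from None

    def write_tsv(self, path) -> None:
        if sp.issparse(self.values) and len(self.ids) > 5000:
            coo = sp.triu(self.values.tocoo())
            pd.DataFrame({
                "id_i": self.ids[coo.row], "id_j": self.ids[coo.col],
                "value": coo.data,
            }).to_csv(path, sep="\t", index=False, float_format="%.10g")
        else:
            df = pd.DataFrame(self.to_dense(), columns=self.ids)
            df.insert(0, "id", self.ids)
            df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def compute_inbreeding(pedigree: Pedigree) -> pd.Series:
    """Inbreeding coefficient f_i = 0.5 a(sire_i, dam_i) for every animal.

    Memoised recursion on the additive relationship; founders and animals
    with an unknown parent get f = 0.  Matches diag(A) - 1 of the tabular
    method exactly.
    """
    sire, dam = pedigree.sire, pedigree.dam
    n = len(pedigree)
    f = np.zeros(n)
    memo: dict = {}

    def a(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return 1.0 + f[i]
        if i > j:
            i, j = j, i
        key = (i, j)
        val = memo.get(key)
        if val is None:
            # j is the younger animal: expand through its parents
            val = 0.5 * (a(i, sire[j]) + a(i, dam[j]))
            memo[key] = val
        return val

    for k in range(n):
        if sire[k] >= 0 and dam[k] >= 0:
            f[k] = 0.5 * a(sire[k], dam[k])
    return pd.Series(f, index=pedigree.ids, name="f")


def build_A(pedigree: Pedigree, subset=None) -> RelationshipMatrix:
    """Numerator relationship matrix A (full) or its subset block (A22).

    The full matrix uses the tabular method.  A subset is computed against
    the full pedigree without forming dense A: columns of A are obtained by
    solving ``A^-1 x = e_j`` with the sparse Henderson inverse.
    """
    n = len(pedigree)
    if subset is None:
        A = np.zeros((n, n))
        sire, dam = pedigree.sire, pedigree.dam
        for i in range(n):
            s, d = sire[i], dam[i]
            asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
            A[i, i] = 1.0 + 0.5 * asd
        return RelationshipMatrix("A", pedigree.ids.copy(), A)

    idx = pedigree.index_of(subset)
    ainv = build_A_inverse(pedigree)
    lu = sp.linalg.splu(ainv.values.tocsc(), permc_spec="MMD_AT_PLUS_A",
                        diag_pivot_thresh=0.0,
                        options={"SymmetricMode": True})
    rhs = np.zeros((n, len(idx)))
    rhs[idx, np.arange(len(idx))] = 1.0
    cols = lu.solve(rhs)
    block = cols[idx]
    block = 0.5 * (block + block.T)
    return RelationshipMatrix("A22", np.asarray(subset, dtype=object), block)


def build_A_inverse(
    pedigree: Pedigree, inbreeding: pd.Series | None = None
) -> RelationshipMatrix:
    """Sparse A-inverse by Henderson's rules, accounting for inbreeding.

    Each animal i contributes 1/d_i spread over (i, sire, dam) with
    d_i = 0.5 - 0.25 (f_s + f_d) when both parents are known,
    0.75 - 0.25 f_p with one known parent, and 1 for founders.
    """
    if inbreeding is None:
        inbreeding = compute_inbreeding(pedigree)
    f = inbreeding.loc[pedigree.ids].to_numpy(dtype=float)
    n = len(pedigree)
    sire, dam = pedigree.sire, pedigree.dam

    fs = np.where(sire >= 0, f[np.maximum(sire, 0)], 0.0)
    fd = np.where(dam >= 0, f[np.maximum(dam, 0)], 0.0)
    n_known = (sire >= 0).astype(int) + (dam >= 0).astype(int)
    d = np.where(
        n_known == 2, 0.5 - 0.25 * (fs + fd),
        np.where(n_known == 1, 0.75 - 0.25 * (fs + fd), 1.0),
    )
    alpha = 1.0 / d

    rows, cols, vals = [np.arange(n)], [np.arange(n)], [alpha]
    for parent in (sire, dam):
        known = parent >= 0
        i, p, a = np.flatnonzero(known), parent[known], alpha[known]
        rows += [i, p, p]
        cols += [p, i, p]
        vals += [-0.5 * a, -0.5 * a, 0.25 * a]
    # cross parent-parent terms when both parents are known
    both = (sire >= 0) & (dam >= 0)
    s, dd, a2 = sire[both], dam[both], alpha[both]
    rows += [s, dd]
    cols += [dd, s]
    vals += [0.25 * a2, 0.25 * a2]

    ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return RelationshipMatrix("A_inverse", pedigree.ids.copy(), ainv,
                              {"inbreeding": f})


def build_G(
    genotypes: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from a complete genotype matrix.

    Each SNP column is centred by twice its allele frequency (estimated
    from all genotyped animals unless supplied) and
    ``G = Z Z' / (2 sum p_i (1 - p_i))``.
    """
    if not genotypes.is_complete:
        raise ValueError("build_G requires a complete (imputed) genotype matrix")
    if freqs is None:
        freqs = genotypes.codes.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: G denominator 2*sum(p(1-p)) is zero")
    Z = genotypes.codes - 2.0 * freqs
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix("G", genotypes.animal_ids.copy(), G,
                              {"denominator": denom})


def blend_G(
    G: RelationshipMatrix, A22: RelationshipMatrix, w: float = 0.9
) -> RelationshipMatrix:
    """Blend G with the pedigree block: ``G_w = w G + (1 - w) A22``."""
    if not 0.0 < w <= 1.0:
        raise ValueError("blend weight w must lie in (0, 1]")
    if len(G.ids) != len(A22.ids) or np.any(G.ids != A22.ids):
        raise ValueError("G and A22 must be indexed by the same animals")
    vals = w * G.to_dense() + (1.0 - w) * A22.to_dense()
    meta = dict(G.metadata)
    meta["blend_weight"] = w
    return RelationshipMatrix("G_blended", G.ids.copy(), vals, meta)


def invert_dense(mat: RelationshipMatrix, kind: str) -> RelationshipMatrix:
    """Cholesky inverse of a dense relationship matrix."""
    m = mat.to_dense()
    try:
        L = np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"{mat.kind} is not positive definite and cannot be inverted; "
            "blend G with A22 (w < 1) or add a ridge before inverting"
        ) from None
    inv = np.linalg.inv(L)
    vals = inv.T @ inv
    return RelationshipMatrix(kind, mat.ids.copy(), 0.5 * (vals + vals.T),
                              dict(mat.metadata))


def build_H_inverse(
    A_inv: RelationshipMatrix,
    G_inv: RelationshipMatrix,
    A22_inv: RelationshipMatrix,
    genotyped_ids,
) -> RelationshipMatrix:
    """Single-step H-inverse: A-inverse plus (G^-1 - A22^-1) on the
    genotyped block, zeros elsewhere.

    Row/column order follows the pedigree order of ``A_inv``; the
    genotyped block is located by id and need not be contiguous.
    """
    genotyped_ids = np.asarray(genotyped_ids, dtype=object)
    if len(G_inv.ids) != len(genotyped_ids) or np.any(G_inv.ids != genotyped_ids):
        raise ValueError("G_inv must be indexed by genotyped_ids")
    if np.any(A22_inv.ids != G_inv.ids):
        raise ValueError("G_inv and A22_inv must be indexed identically")
    idx = A_inv.index_of(genotyped_ids)
    diff = G_inv.to_dense() - A22_inv.to_dense()
    update = sp.coo_matrix(
        (diff.ravel(), (np.repeat(idx, len(idx)), np.tile(idx, len(idx)))),
        shape=A_inv.values.shape,
    )
    hinv = (A_inv.values + update).tocsr()
    return RelationshipMatrix("H_inverse", A_inv.ids.copy(), hinv,
                              {"genotyped_ids": genotyped_ids})
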