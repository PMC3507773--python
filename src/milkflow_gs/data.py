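"""Core data containers: pedigree and SNP genotype matrix.

Both containers are thin wrappers around numpy arrays with id bookkeeping,
plus readers/writers for the plain-text formats used throughout the package
(CSV pedigree with ``0`` for unknown parents, TSV genotypes with ``NA`` for
missing calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = "0"


@dataclass
class Pedigree:
    """Ordered pedigree: parents always appear before their offspring.

    ``sire`` and ``dam`` hold integer positions into ``ids`` (-1 = unknown).
    """

    ids: np.ndarray  # array of str
    sire: np.ndarray  # int positions, -1 unknown
    dam: np.ndarray
    sex: np.ndarray  # 'M' / 'F'
    generation: np.ndarray  # int >= 0
    _index: dict = field(default=None, repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=object)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("pedigree ids are not unique")
        n = len(self.ids)
        for name, parent in (("sire", self.sire), ("dam", self.dam)):
            if np.any(parent >= np.arange(n)):
                bad = int(np.argmax(parent >= np.arange(n)))
                raise ValueError(
                    f"pedigree not topologically ordered: {name} of "
                    f"{self.ids[bad]!r} does not precede it"
                )

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in animal_ids], dtype=np.int64)
        except KeyError as err:
            raise KeyError(f"animal {err.args[0]!r} not in pedigree") from None

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from (animal, sire, dam, sex, generation) tuples.

        Unknown parents are the token ``"0"``.
        """
        records = list(records)
        ids = [str(r[0]) for r in records]
        index = {a: i for i, a in enumerate(ids)}
        sire = np.full(len(ids), -1, dtype=np.int64)
        dam = np.full(len(ids), -1, dtype=np.int64)
        sex, gen = [], []
        for i, r in enumerate(records):
            s, d = str(r[1]), str(r[2])
            if s != UNKNOWN:
                sire[i] = index[s]
            if d != UNKNOWN:
                dam[i] = index[d]
            sex.append(r[3])
            gen.append(int(r[4]))
        return cls(np.array(ids, dtype=object), sire, dam,
                   np.array(sex, dtype=object), np.array(gen))

    def to_frame(self) -> pd.DataFrame:
        sid = np.where(self.sire >= 0, self.ids[np.maximum(self.sire, 0)], UNKNOWN)
        did = np.where(self.dam >= 0, self.ids[np.maximum(self.dam, 0)], UNKNOWN)
        return pd.DataFrame(
            {"id": self.ids, "sire": sid, "dam": did,
             "sex": self.sex, "generation": self.generation}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype=str)
        return cls.from_records(
            df[["id", "sire", "dam", "sex", "generation"]].itertuples(index=False)
        )


@dataclass
class GenotypeMatrix:
    """Animals x SNPs genotype dosages.

    ``codes`` holds counts of the reference allele in {0, 1, 2}; missing
    calls are NaN.  After mean-dosage imputation entries may be any real in
    [0, 2].
    """

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    codes: np.ndarray  # float, NaN = missing
    chrom: np.ndarray = None
    pos: np.ndarray = None
    _index: dict = field(default=None, repr=False)

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError("codes shape inconsistent with id lists")
        ok = np.isnan(self.codes) | ((self.codes >= 0) & (self.codes <= 2))
        if not np.all(ok):
            raise ValueError("genotype codes must lie in [0, 2] or be NaN")
        if self.chrom is None:
            self.chrom = np.ones(len(self.snp_ids), dtype=np.int64)
        if self.pos is None:
            self.pos = np.arange(1, len(self.snp_ids) + 1, dtype=np.int64)
        self._index = {a: i for i, a in enumerate(self.animal_ids)}

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def is_complete(self) -> bool:
        return not np.any(np.isnan(self.codes))

    def row_index(self, animal_ids) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in animal_ids], dtype=np.int64)
        except KeyError as err:
            raise KeyError(f"animal {err.args[0]!r} not genotyped") from None

    def subset_animals(self, animal_ids) -> "GenotypeMatrix":
        rows = self.row_index(animal_ids)
        return GenotypeMatrix(
            np.asarray(animal_ids, dtype=object), self.snp_ids.copy(),
            self.codes[rows].copy(), self.chrom.copy(), self.pos.copy()
        )

    def subset_snps(self, keep_mask: np.ndarray) -> "GenotypeMatrix":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return GenotypeMatrix(
            self.animal_ids.copy(), self.snp_ids[keep_mask],
            self.codes[:, keep_mask].copy(),
            self.chrom[keep_mask], self.pos[keep_mask]
        )

    def write_tsv(self, path, map_path=None) -> None:
        df = pd.DataFrame(self.codes, columns=self.snp_ids)
        df.insert(0, "id", self.animal_ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")
        if map_path is not None:
            pd.DataFrame(
                {"snp": self.snp_ids, "chrom": self.chrom, "pos": self.pos}
            ).to_csv(map_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, map_path=None) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", na_values="NA")
        ids = df["id"].astype(str).to_numpy(dtype=object)
        snps = np.array(df.columns[1:], dtype=object)
        codes = df.iloc[:, 1:].to_numpy(dtype=float)
        chrom = pos = None
        if map_path is not None:
            m = pd.read_csv(map_path, sep="\t").set_index("snp").loc[snps]
            chrom, pos = m["chrom"].to_numpy(), m["pos"].to_numpy()
        return cls(ids, snps, codes, chrom, pos)
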