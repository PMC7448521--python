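"""Core data containers and file I/O.

The scan tests operate on variant-level score statistics: a score vector
``U`` and its covariance ``V``, obtained either from external software
(summary-statistic mode) or computed here from individual-level data under
a linear null model.  Variants carry a chromosomal position, a minor allele
frequency (MAF), a cumulative minor allele count (MAC), and optionally 3D
coordinates on a protein structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("protscan")

UNMAPPED = "UNMAPPED"

__all__ = [
    "VariantTable",
    "SpatialMap",
    "SummaryStats",
    "IndividualData",
    "UNMAPPED",
    "read_summary_stats",
    "write_summary_stats",
    "read_spatial_map",
    "write_spatial_map",
    "compute_score_stats",
    "variant_table_from_genotypes",
]


@dataclass
class VariantTable:
    """Per-variant identity, chromosomal position, MAF and MAC.

    All arrays are aligned; ``variant_id`` entries must be unique.
    """

    variant_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray
    mac: np.ndarray

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        self.mac = np.asarray(self.mac, dtype=np.int64)
        n = len(self.variant_id)
        if not all(len(a) == n for a in (self.chrom, self.pos, self.maf, self.mac)):
            raise ValueError("VariantTable columns have inconsistent lengths")
        if len(set(self.variant_id)) != n:
            raise ValueError("duplicate variant ids")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValueError("MAF must lie in (0, 0.5]")
        if np.any(self.mac < 0):
            raise ValueError("MAC must be non-negative")

    def __len__(self) -> int:
        return len(self.variant_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "maf": self.maf,
                "mac": self.mac,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "VariantTable":
        return cls(
            variant_id=df["variant_id"].to_numpy(dtype=object),
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(),
            maf=df["maf"].to_numpy(),
            mac=df["mac"].to_numpy(),
        )

    def index_of(self, variant_ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variant_id)}
        return np.array([lookup[v] for v in variant_ids], dtype=np.intp)


@dataclass
class SpatialMap:
    """Per-variant 3D coordinates and structure assignment.

    ``structure_id[i]`` is :data:`UNMAPPED` for variants without structural
    information; their coordinate rows are NaN.  Each mapped variant belongs
    to exactly one structure.
    """

    structure_id: np.ndarray  # object array, UNMAPPED allowed
    coords: np.ndarray  # (m, d) float, NaN rows for unmapped

    def __post_init__(self) -> None:
        self.structure_id = np.asarray(self.structure_id, dtype=object)
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[0] != len(self.structure_id):
            raise ValueError("coords and structure_id lengths differ")

    def __len__(self) -> int:
        return len(self.structure_id)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @property
    def mapped(self) -> np.ndarray:
        return np.array([s != UNMAPPED for s in self.structure_id], dtype=bool)

    def structures(self) -> list[str]:
        """Distinct structure ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.structure_id:
            if s != UNMAPPED:
                seen.setdefault(s, None)
        return list(seen)

    def structure_indices(self, structure_id: str) -> np.ndarray:
        return np.flatnonzero(
            np.array([s == structure_id for s in self.structure_id])
        )

    @classmethod
    def all_unmapped(cls, m: int, dim: int = 3) -> "SpatialMap":
        return cls(
            structure_id=np.array([UNMAPPED] * m, dtype=object),
            coords=np.full((m, dim), np.nan),
        )


@dataclass
class SummaryStats:
    """Variant-level score vector U and its covariance V.

    The contract is that ``U[j] / sqrt(V[j, j])`` is the standard score
    Z-statistic for variant j under the null.
    """

    U: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float).ravel()
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        m = self.U.size
        if self.V.shape != (m, m):
            raise ValueError(f"V must be {m}x{m}, got {self.V.shape}")
        if not np.allclose(self.V, self.V.T, atol=1e-8 * max(1.0, np.abs(self.V).max())):
            raise ValueError("V is not symmetric")
        scale = max(1.0, float(np.abs(np.diag(self.V)).max(initial=0.0)))
        if np.any(np.diag(self.V) < -1e-8 * scale):
            raise ValueError("V has negative diagonal entries")

    @property
    def m(self) -> int:
        return self.U.size


@dataclass
class IndividualData:
    """Individual-level inputs: genotype dosages, trait, covariates.

    ``G`` holds minor-allele counts in {0,1,2}; ``Z`` must include an
    intercept column.  Missing entries are rejected.
    """

    G: np.ndarray  # (n, m)
    y: np.ndarray  # (n,)
    Z: np.ndarray  # (n, q)

    def __post_init__(self) -> None:
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        n = self.y.size
        if self.G.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("sample size inconsistent across G, y, Z")
        for name, a in (("G", self.G), ("y", self.y), ("Z", self.Z)):
            if np.isnan(a).any():
                raise ValueError(f"missing values in {name} are not supported")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def m(self) -> int:
        return self.G.shape[1]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = ["variant_id", "chrom", "pos", "maf", "mac", "U"]


def read_summary_stats(score_path, cov_path) -> tuple[VariantTable, SummaryStats]:
    """Read a tab-delimited score file and a covariance file.

    The score file needs header columns ``variant_id chrom pos maf mac U``.
    The covariance file is either a dense whitespace-delimited m-by-m matrix
    or long format ``id_i id_j v`` (header optional); absent off-diagonal
    pairs in long format are taken as zero and entries are symmetrised.
    """
    df = pd.read_csv(score_path, sep="\t", dtype={"variant_id": str, "chrom": str})
    missing = [c for c in _SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score file {score_path} lacks columns: {missing}")
    variants = VariantTable.from_dataframe(df)
    U = df["U"].to_numpy(dtype=float)
    m = len(variants)
    V = _read_covariance(cov_path, variants, m)
    return variants, SummaryStats(U=U, V=V)


def _read_covariance(cov_path, variants: VariantTable, m: int) -> np.ndarray:
    with open(cov_path) as fh:
        first = fh.readline().split()
    id_set = set(variants.variant_id)
    is_long = (
        len(first) == 3
        and (first[0] in id_set or (first[0], first[1]) == ("id_i", "id_j"))
    )
    if is_long:
        cov = pd.read_csv(
            cov_path,
            sep="\t",
            names=["id_i", "id_j", "v"],
            header=0 if first[0] == "id_i" else None,
            dtype={"id_i": str, "id_j": str},
        )
        unknown = set(cov["id_i"]) | set(cov["id_j"]) - id_set
        unknown -= id_set
        if unknown:
            raise ValueError(f"covariance file references unknown variants: {sorted(unknown)[:5]}")
        V = np.zeros((m, m))
        i = variants.index_of(cov["id_i"])
        j = variants.index_of(cov["id_j"])
        V[i, j] = cov["v"].to_numpy(dtype=float)
        # symmetrise: keep explicit entries, mirror missing ones
        V = np.where(V == 0.0, V.T, V)
        if not np.allclose(V, V.T, atol=1e-8):
            raise ValueError("long-format covariance has inconsistent (i,j)/(j,i) entries")
        return V
    V = np.loadtxt(cov_path, ndmin=2)
    if V.shape != (m, m):
        raise ValueError(f"dense covariance is {V.shape}, expected ({m}, {m})")
    if not np.allclose(V, V.T, atol=1e-8 * max(1.0, np.abs(V).max())):
        raise ValueError("dense covariance matrix is not symmetric")
    return 0.5 * (V + V.T)


def write_summary_stats(variants: VariantTable, stats: SummaryStats, score_path, cov_path) -> None:
    """Write score and dense covariance files in the formats read back by
    :func:`read_summary_stats`.  Round-trips numerics to better than 1e-12."""
    df = variants.to_dataframe()
    df["U"] = stats.U
    df.to_csv(score_path, sep="\t", index=False, float_format="%.17g")
    np.savetxt(cov_path, stats.V, fmt="%.17g")


def read_spatial_map(path, variants: VariantTable) -> SpatialMap:
    """Read variant 3D coordinates (``variant_id structure_id x y z``).

    Variants absent from the file, or with empty coordinate fields, are
    unmapped.  A variant listed under several structures is kept on the
    highest-priority one: experimental over computational model (structure
    ids prefixed ``mod``/``model`` count as computational), then the
    structure mapping more variants, then the lexicographically smallest id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "structure_id": str})
    for col in ("variant_id", "structure_id", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"spatial map {path} lacks column {col!r}")
    id_set = set(variants.variant_id)
    unknown = ~df["variant_id"].isin(id_set)
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} spatial-map rows reference variants not in the "
            "variant table; dropped",
            stacklevel=2,
        )
        df = df[~unknown]
    df = df.dropna(subset=["x", "y", "z"])
    try:
        df[["x", "y", "z"]].astype(float)
    except ValueError as exc:  # pragma: no cover - pandas already coerces
        raise ValueError(f"non-numeric coordinates in {path}") from exc

    n_mapped = df.groupby("structure_id")["variant_id"].nunique().to_dict()

    def priority(sid: str) -> tuple:
        computational = sid.lower().startswith(("model", "mod"))
        return (computational, -n_mapped.get(sid, 0), sid)

    m = len(variants)
    structure_id = np.array([UNMAPPED] * m, dtype=object)
    coords = np.full((m, 3), np.nan)
    lookup = {v: i for i, v in enumerate(variants.variant_id)}
    for vid, grp in df.groupby("variant_id", sort=False):
        if grp["structure_id"].nunique() > 1:
            logger.warning(
                "variant %s maps to structures %s; keeping highest priority",
                vid,
                sorted(grp["structure_id"].unique()),
            )
        row = grp.loc[grp["structure_id"].map(priority).sort_values().index[0]]
        i = lookup[vid]
        structure_id[i] = row["structure_id"]
        coords[i] = [float(row["x"]), float(row["y"]), float(row["z"])]
    return SpatialMap(structure_id=structure_id, coords=coords)


def write_spatial_map(variants: VariantTable, smap: SpatialMap, path) -> None:
    rows = []
    for i, vid in enumerate(variants.variant_id):
        if smap.structure_id[i] == UNMAPPED:
            continue
        x, y, z = (smap.coords[i].tolist() + [np.nan] * 3)[:3]
        rows.append((vid, smap.structure_id[i], x, y, z))
    pd.DataFrame(rows, columns=["variant_id", "structure_id", "x", "y", "z"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Score statistics from individual-level data
# ---------------------------------------------------------------------------


def compute_score_stats(data: IndividualData) -> SummaryStats:
    """Score statistics for a quantitative trait under a linear null model.

    Fits y = Z gamma + eps by least squares, then

        U = G' r / sigma2_hat,
        V = (G'G - G'Z (Z'Z)^-1 Z'G) / sigma2_hat,

    with r the null residuals and sigma2_hat = RSS / (n - rank(Z)).
    U[j] / sqrt(V[j,j]) is the score Z-statistic for variant j.
    """
    G, y, Z = data.G, data.y, data.Z
    n = data.n
    ZtZ = Z.T @ Z
    rank = np.linalg.matrix_rank(ZtZ)
    if rank < Z.shape[1]:
        raise np.linalg.LinAlgError("covariate matrix Z'Z is singular")
    gamma = np.linalg.solve(ZtZ, Z.T @ y)
    r = y - Z @ gamma
    dof = n - rank
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(r @ r) / dof
    ZtG = Z.T @ G
    Vtilde = G.T @ G - ZtG.T @ np.linalg.solve(ZtZ, ZtG)
    Vtilde = 0.5 * (Vtilde + Vtilde.T)
    diag = np.diag(Vtilde).copy()
    mono = diag <= 1e-10 * max(1.0, diag.max(initial=0.0))
    if mono.any():
        logger.warning("%d monomorphic variant(s): V[j,j]=0", int(mono.sum()))
        # zero out roundoff on degenerate variants
        Vtilde[mono, :] = 0.0
        Vtilde[:, mono] = 0.0
    return SummaryStats(U=(G.T @ r) / sigma2, V=Vtilde / sigma2)


def variant_table_from_genotypes(
    G: np.ndarray,
    variant_id=None,
    chrom="1",
    pos=None,
) -> VariantTable:
    """Build a :class:`VariantTable` from a dosage matrix, recomputing MAF
    and MAC from the sample (single source of truth when individual-level
    data are supplied).  Columns are assumed minor-allele oriented."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    n, m = G.shape
    mac = G.sum(axis=0).astype(np.int64)
    maf = mac / (2.0 * n)
    if variant_id is None:
        variant_id = [f"v{j + 1}" for j in range(m)]
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    return VariantTable(
        variant_id=np.asarray(variant_id, dtype=object),
        chrom=np.asarray([chrom] * m, dtype=object),
        pos=pos,
        maf=np.clip(maf, 1e-12, 0.5),
        mac=mac,
    )
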