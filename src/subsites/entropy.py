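"""Specificity matrices and cleavage entropy.

A specificity matrix gives, for each of the eight substrate positions
P4..P4', the occurrence n_ij of each of the 20 amino acids among a
protease's known substrates. The per-position cleavage entropy is the
base-20 Shannon entropy

    H(j) = -sum_i n_ij * log20(n_ij),        0 <= H(j) <= 1,

with the 0*log(0) = 0 continuity convention: 0 means absolute prevalence
of one amino acid, 1 equal usage of all twenty. The total cleavage
entropy is the sum over the eight positions, H_cleavage in [0, 8].
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .constants import POSITION_ORDER, STANDARD_AA1
from .errors import SubsitesError


@dataclass
class SpecificityMatrix:
    """20 x 8 occurrence-fraction table (rows: amino acids, columns P4..P4')."""

    fractions: pd.DataFrame
    substrate_count: float = 0.0
    family_id: str = ""

    def __post_init__(self) -> None:
        f = self.fractions
        if list(f.columns) != list(POSITION_ORDER):
            raise SubsitesError("matrix columns must be P4..P4'")
        if sorted(f.index) != sorted(STANDARD_AA1):
            raise SubsitesError("matrix rows must be the 20 standard amino acids")
        if (f.values < 0).any():
            raise SubsitesError("negative matrix entries")
        sums = f.values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise SubsitesError("columns must each sum to 1 after normalization")

    def column(self, position: str) -> np.ndarray:
        return self.fractions[position].to_numpy()


@dataclass
class EntropyProfile:
    H: dict[str, float]  # position -> H(j)
    H_cleavage: float

    def vector(self) -> np.ndarray:
        return np.array([self.H[p] for p in POSITION_ORDER])


def load_specificity_matrix(
    table: str,
    counts_or_fractions: str = "auto",
    family_id: str = "",
    sep: str = None,
) -> SpecificityMatrix:
    """Parse a delimited 20 x 8 matrix (rows = 1-letter amino acids,
    columns = P4..P4'). Counts are converted to fractions column-wise;
    'auto' treats column sums within 1e-6 of 1 as fractions."""
    df = pd.read_csv(io.StringIO(table), sep=sep or r"\s+|,|\t", engine="python",
                     index_col=0)
    df.index = [str(i).strip().upper() for i in df.index]
    df.columns = [str(c).strip() for c in df.columns]
    bad = set(df.index) - set(STANDARD_AA1)
    if bad:
        raise SubsitesError(f"unsupported amino-acid letters {sorted(bad)}")
    if df.shape != (20, 8):
        raise SubsitesError(f"expected a 20 x 8 matrix, got {df.shape}")
    df = df.reindex(index=sorted(STANDARD_AA1), columns=list(POSITION_ORDER))
    if df.isna().any().any():
        raise SubsitesError("matrix is missing rows or positions P4..P4'")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise SubsitesError("negative matrix entries")
    col_sums = values.sum(axis=0)
    if (col_sums <= 0).any():
        raise SubsitesError("column with zero total occurrences")
    if counts_or_fractions == "fractions" or (
        counts_or_fractions == "auto" and np.allclose(col_sums, 1.0, atol=1e-6)
    ):
        substrate_count = 0.0
        fractions = values / col_sums  # renormalize away rounding noise
    else:
        substrate_count = float(col_sums.max())
        fractions = values / col_sums
    return SpecificityMatrix(
        pd.DataFrame(fractions, index=df.index, columns=df.columns),
        substrate_count,
        family_id,
    )


def position_entropy(column: np.ndarray) -> float:
    """Base-20 Shannon entropy of one specificity column (0*log0 = 0)."""
    col = np.asarray(column, dtype=float)
    if col.size != 20:
        raise SubsitesError("a specificity column has 20 entries")
    if not np.isclose(col.sum(), 1.0, atol=1e-9):
        raise SubsitesError("column fractions must sum to 1")
    nz = col[col > 0]
    return float(-(nz * np.log(nz) / np.log(20.0)).sum() + 0.0)


def cleavage_entropy(matrix: SpecificityMatrix) -> EntropyProfile:
    """Per-position entropies and their sum over P4..P4'."""
    H = {p: position_entropy(matrix.column(p)) for p in POSITION_ORDER}
    return EntropyProfile(H, float(sum(H.values())))


def spearman_per_position(
    observable_profiles: list[np.ndarray],
    entropy_profiles: list[np.ndarray],
) -> float:
    """Average Spearman rank correlation over paired structures.

    Each pair contributes the Spearman rho between the observable's eight
    per-position averages and the entropy profile H(j). Constant vectors
    leave rho undefined; such structures are dropped with a warning.
    """
    if len(observable_profiles) != len(entropy_profiles):
        raise SubsitesError("profile lists must be paired")
    rhos = []
    for i, (obs, ent) in enumerate(zip(observable_profiles, entropy_profiles)):
        obs = np.asarray(obs, dtype=float)
        ent = np.asarray(ent, dtype=float)
        if np.ptp(obs) == 0 or np.ptp(ent) == 0:
            warnings.warn(
                f"structure {i}: constant profile, Spearman undefined; dropped",
                stacklevel=2,
            )
            continue
        rho, _ = spearmanr(obs, ent)
        rhos.append(float(rho))
    if not rhos:
        raise SubsitesError("no structure yielded a defined correlation")
    return float(np.mean(rhos))
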