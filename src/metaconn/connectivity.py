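"""Group-level metabolic connectivity and edge-wise group comparison.

For each treatment group, regional uptake values are correlated across
subjects (Spearman) to give an R x R weighted undirected connectivity
matrix.  Correlations are variance-stabilised with the Fisher transform

    z = 1/2 ln((1 + rho) / (1 - rho))

and each edge is compared between two groups with the two-sample
normal statistic

    Z = (z1 - z2) / sqrt(1/(n1 - 3) + 1/(n2 - 3)),

with Benjamini-Hochberg FDR control over the R(R-1)/2 edges of the
contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import RegionSet, validate_region_sets_match
from .tables import UptakeTable

#: |rho| clamp applied before the Fisher transform, which diverges at +-1
RHO_CLAMP = 1.0 - 1e-7


def rank_correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix of a subjects x regions array.

    Average ranks for ties (standard Spearman), Pearson on the ranks.
    Columns with zero variance yield NaN rows/columns (flagged upstream).
    """
    values = np.asarray(values, float)
    ranks = stats.rankdata(values, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, float)
    np.fill_diagonal(rho, 1.0)
    return rho


@dataclass
class GroupConnectivity:
    """Spearman connectivity of one group: rho, its Fisher z, and n."""

    group: str
    n: int
    rho: np.ndarray
    region_set: RegionSet
    undefined_regions: list[str] = field(default_factory=list)

    @property
    def z(self) -> np.ndarray:
        z = fisher_z(self.rho)
        np.fill_diagonal(z, 0.0)
        return z

    def rho_frame(self) -> pd.DataFrame:
        codes = self.region_set.codes
        return pd.DataFrame(self.rho, index=codes, columns=codes)

    def to_csv(self, path) -> None:
        self.rho_frame().to_csv(path)


def spearman_matrix(table: UptakeTable, group: str) -> GroupConnectivity:
    """Group connectivity matrix from an uptake table.

    Requires at least 4 subjects (the downstream Z test needs n > 3).
    A region constant across subjects has undefined rank correlations;
    its edges are set to NaN and the region is flagged, never zeroed.
    """
    values = table.group_values(group)
    n = values.shape[0]
    if n < 4:
        raise ValueError(f"group {group!r} has n={n}; need >= 4 subjects")
    rho = rank_correlation_matrix(values)
    constant = np.ptp(values, axis=0) == 0
    undefined = [c for c, flag in zip(table.region_set.codes, constant) if flag]
    if undefined:
        idx = np.where(constant)[0]
        rho[idx, :] = np.nan
        rho[:, idx] = np.nan
        np.fill_diagonal(rho, 1.0)
    return GroupConnectivity(group, n, rho, table.region_set, undefined)


def fisher_z(rho):
    """Fisher r-to-z transform, z = arctanh(rho), with |rho| clamped.

    The clamp at 1 - 1e-7 keeps perfectly (anti)correlated edges finite,
    which small-n rank correlations produce routinely.  Odd function.
    """
    rho = np.asarray(rho, float)
    if np.any(np.abs(rho[np.isfinite(rho)]) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    return np.arctanh(np.clip(rho, -RHO_CLAMP, RHO_CLAMP))


def edge_z_test(z1, z2, n1: int, n2: int):
    """Two-sample Z test for a difference of Fisher-transformed correlations.

    Z = (z1 - z2)/sqrt(1/(n1-3) + 1/(n2-3)); two-sided p = 2 Phi(-|Z|).
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError(
            f"need n > 3 in both groups (got {n1}, {n2}): the sampling "
            "variance of Fisher z is 1/(n - 3)"
        )
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    Z = (np.asarray(z1, float) - np.asarray(z2, float)) / se
    p = 2.0 * stats.norm.sf(np.abs(Z))
    return Z, p


@dataclass
class EdgeComparison:
    """Edge-wise contrast of two group connectivity matrices.

    ``edges`` is a long-format table over unordered region pairs with
    columns region_a, region_b, rho_1, rho_2, z_1, z_2, Z, p, q,
    significant.  The sign convention is first group minus second.
    ``excluded`` lists pairs dropped because a correlation was undefined.
    """

    group_1: str
    group_2: str
    n_1: int
    n_2: int
    alpha: float
    edges: pd.DataFrame
    excluded: list[tuple[str, str]]
    region_set: RegionSet

    @property
    def n_tested(self) -> int:
        return len(self.edges)

    @property
    def n_significant(self) -> int:
        return int(self.edges["significant"].sum())

    def significance_mask(self) -> np.ndarray:
        """Symmetric boolean R x R matrix of q < alpha edges."""
        codes = self.region_set.codes
        idx = {c: i for i, c in enumerate(codes)}
        mask = np.zeros((len(codes), len(codes)), bool)
        sig = self.edges[self.edges["significant"]]
        for a, b in zip(sig["region_a"], sig["region_b"]):
            mask[idx[a], idx[b]] = mask[idx[b], idx[a]] = True
        return mask

    def to_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)


def compare_groups(
    conn_1: GroupConnectivity,
    conn_2: GroupConnectivity,
    alpha: float = 0.01,
    variance_inflation: float = 1.0,
) -> EdgeComparison:
    """Edge-wise Z tests with Benjamini-Hochberg FDR over all edges.

    ``variance_inflation`` scales the 1/(n-3) variances; 1.0 follows the
    classical Pearson-derived form, ~1.06 is the conventional adjustment
    for Spearman-based z.  Edges undefined in either group are excluded
    from both testing and the multiplicity count, and reported.
    """
    validate_region_sets_match(conn_1.region_set, conn_2.region_set)
    codes = conn_1.region_set.codes
    r = len(codes)
    iu, ju = np.triu_indices(r, k=1)
    rho1 = conn_1.rho[iu, ju]
    rho2 = conn_2.rho[iu, ju]
    defined = np.isfinite(rho1) & np.isfinite(rho2)
    excluded = [(codes[i], codes[j]) for i, j, d in zip(iu, ju, defined) if not d]

    z1 = fisher_z(rho1[defined])
    z2 = fisher_z(rho2[defined])
    se = np.sqrt(
        variance_inflation * (1.0 / (conn_1.n - 3) + 1.0 / (conn_2.n - 3))
    )
    Z = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(np.abs(Z))
    if p.size:
        reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    else:
        reject, q = np.zeros(0, bool), np.zeros(0)

    edges = pd.DataFrame(
        {
            "region_a": [codes[i] for i, d in zip(iu, defined) if d],
            "region_b": [codes[j] for j, d in zip(ju, defined) if d],
            "rho_1": rho1[defined],
            "rho_2": rho2[defined],
            "z_1": z1,
            "z_2": z2,
            "Z": Z,
            "p": p,
            "q": q,
            "significant": reject,
        }
    )
    return EdgeComparison(
        conn_1.group, conn_2.group, conn_1.n, conn_2.n, alpha, edges,
        excluded, conn_1.region_set,
    )
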