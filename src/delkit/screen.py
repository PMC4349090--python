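"""Stress-screen scoring: spot-assay sensitivity calls, ordinal encoding,
multi-stress counting, complete-linkage clustering and clustered-table export.

Strains are spotted as 10-fold serial dilutions next to wild type; the
readout per strain x condition is the deepest dilution still showing growth.
Relative to the wild-type depth on the same plate a strain is called

* very_sensitive (code  2): no growth at all while wild type grows;
* sensitive      (code  1): grows, but >= 2 dilution factors shallower;
* not_sensitive  (code  0): within one dilution factor of wild type;
* resistant      (code -1): grows deeper than wild type.

The encoded strain x condition matrix is clustered hierarchically with
complete linkage and exported in the CDT/GTR clustered-data-table text
formats understood by Java TreeView.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


class ScreenError(ValueError):
    """Raised on malformed screen inputs."""


class SensitivityCall(Enum):
    VERY_SENSITIVE = ("very_sensitive", 2)
    SENSITIVE = ("sensitive", 1)
    NOT_SENSITIVE = ("not_sensitive", 0)
    RESISTANT = ("resistant", -1)

    def __init__(self, label: str, code: int) -> None:
        self.label = label
        self.code = code

    @classmethod
    def from_label(cls, label: str) -> "SensitivityCall":
        for call in cls:
            if call.label == label:
                return call
        raise ScreenError(f"unknown sensitivity label {label!r}")

    @classmethod
    def from_code(cls, code: int) -> "SensitivityCall":
        for call in cls:
            if call.code == code:
                return call
        raise ScreenError(f"unknown sensitivity code {code!r}")


CODES = tuple(c.code for c in SensitivityCall)


@dataclass(frozen=True)
class Condition:
    name: str
    kind: str   # compound | temperature | medium
    dose: str   # as applied, e.g. "25 uM" or "19 C"


@dataclass(frozen=True)
class StressPanel:
    """An ordered stress-condition panel."""

    conditions: tuple[Condition, ...]

    def __len__(self) -> int:
        return len(self.conditions)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.conditions]

    @staticmethod
    def canonical() -> "StressPanel":
        """The 16-condition screen panel: 13 compounds + two temperatures +
        minimal medium."""
        compounds = [
            ("brefeldin_A", "25 uM"),
            ("bleomycin", "1 ug/ml"),
            ("calcofluor_white", "0.5 mg/ml"),
            ("cycloheximide", "10 ug/ml"),
            ("EGTA", "5 mM"),
            ("hydroxyurea", "7.5 mM"),
            ("KCl", "1 M"),
            ("latrunculin_A", "0.25 uM"),
            ("MBC", "10 ug/ml"),
            ("MMS", "0.01 %"),
            ("SDS", "0.005 %"),
            ("sorbitol", "1.2 M"),
            ("TBZ", "12.5 ug/ml"),
        ]
        conditions = [Condition(n, "compound", d) for n, d in compounds]
        conditions.append(Condition("19C", "temperature", "19 C"))
        conditions.append(Condition("36C", "temperature", "36 C"))
        conditions.append(Condition("minimal_medium", "medium", "EMM2 + ade ura leu"))
        return StressPanel(conditions=tuple(conditions))


# Drug subsets used for focused strain lists.
DNA_METABOLISM_CONDITIONS = ("hydroxyurea", "bleomycin", "MMS")
ACTIN_CONDITIONS = ("latrunculin_A",)


def classify_sensitivity(mutant_depth: int, wt_depth: int) -> SensitivityCall:
    """Call a strain x condition phenotype from spot-assay dilution depths.

    Depths count 10-fold dilution spots showing growth.  wt_depth must be
    positive (a plate where wild type itself failed is uninformative).
    """
    if mutant_depth < 0 or wt_depth < 0:
        raise ScreenError("dilution depths must be non-negative")
    if wt_depth == 0:
        raise ScreenError("wild-type depth 0: uninformative plate")
    if mutant_depth == 0:
        return SensitivityCall.VERY_SENSITIVE
    if mutant_depth > wt_depth:
        return SensitivityCall.RESISTANT
    if wt_depth - mutant_depth >= 2:
        return SensitivityCall.SENSITIVE
    return SensitivityCall.NOT_SENSITIVE


@dataclass
class PhenotypeMatrix:
    """Strains x conditions grid of ordinal sensitivity codes (2/1/0/-1)."""

    data: pd.DataFrame  # int codes, index=strains, columns=conditions

    def __post_init__(self) -> None:
        bad = set(np.unique(self.data.to_numpy())) - set(CODES)
        if bad:
            raise ScreenError(f"matrix contains non-ordinal codes: {sorted(bad)}")

    @property
    def strains(self) -> list[str]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.data.columns)

    def to_labels(self) -> pd.DataFrame:
        return self.data.map(lambda c: SensitivityCall.from_code(int(c)).label)


def encode_matrix(calls: pd.DataFrame) -> PhenotypeMatrix:
    """Numeric 2/1/0/-1 encoding of a strains x conditions label grid."""
    encoded = calls.map(lambda v: SensitivityCall.from_label(str(v)).code)
    return PhenotypeMatrix(data=encoded.astype(int))


def decode_matrix(matrix: PhenotypeMatrix) -> pd.DataFrame:
    return matrix.to_labels()


def score_readouts(readouts: pd.DataFrame) -> PhenotypeMatrix:
    """Score a long-format spot-assay table into a phenotype matrix.

    Expects columns strain, condition, mutant_depth, wt_depth (one row per
    assay).  Repeated measurements of a cell keep the most extreme confirmed
    call (largest |code|, sensitivity winning ties against resistance).
    """
    required = {"strain", "condition", "mutant_depth", "wt_depth"}
    missing = required - set(readouts.columns)
    if missing:
        raise ScreenError(f"readout table missing columns: {sorted(missing)}")
    strains = list(dict.fromkeys(readouts["strain"]))
    conditions = list(dict.fromkeys(readouts["condition"]))
    grid = pd.DataFrame(0, index=strains, columns=conditions, dtype=int)
    for row in readouts.itertuples(index=False):
        call = classify_sensitivity(int(row.mutant_depth), int(row.wt_depth))
        prev = int(grid.at[row.strain, row.condition])
        if (abs(call.code), call.code) > (abs(prev), prev):
            grid.at[row.strain, row.condition] = call.code
    return PhenotypeMatrix(data=grid)


def count_multistress(
    matrix: PhenotypeMatrix,
    k: int,
    mode: str = "any_nonzero",
    denominator: int = 281,
) -> tuple[list[str], int, float]:
    """Strains affected in at least k conditions, with the collection percentage.

    mode="any_nonzero" counts sensitivity or resistance (any nonzero code);
    mode="positive_only" counts sensitivity only (codes 1 and 2).  The
    percentage is computed over `denominator`, by default the published
    collection size of 281 strains.
    """
    if k < 1:
        raise ScreenError("k must be >= 1")
    if mode == "any_nonzero":
        hits = (matrix.data != 0).sum(axis=1)
    elif mode == "positive_only":
        hits = (matrix.data > 0).sum(axis=1)
    else:
        raise ScreenError(f"unknown mode {mode!r}")
    selected = [s for s, n in hits.items() if n >= k]
    pct = 100.0 * len(selected) / denominator
    return selected, len(selected), pct


def select_condition_set(
    matrix: PhenotypeMatrix,
    conditions: list[str] | tuple[str, ...],
    min_calls: tuple[int, ...] = (1, 2),
) -> list[str]:
    """Strains with a qualifying call in at least one of the named conditions.

    Used for the DNA-metabolism drug set (hydroxyurea, bleomycin, MMS) and
    the latrunculin A set; by default a qualifying call is sensitive or
    very sensitive.
    """
    if not conditions:
        raise ScreenError("empty condition set")
    unknown = set(conditions) - set(matrix.conditions)
    if unknown:
        raise ScreenError(f"unknown conditions: {sorted(unknown)}")
    sub = matrix.data[list(conditions)]
    mask = sub.isin(min_calls).any(axis=1)
    return [s for s, m in mask.items() if m]


@dataclass
class ClusterResult:
    """Row (and optionally column) dendrogram over a phenotype matrix."""

    linkage: np.ndarray           # scipy linkage matrix for strains
    leaf_order: list[int]
    strains: list[str]
    metric: str
    col_linkage: np.ndarray | None = None
    col_leaf_order: list[int] | None = None

    @property
    def ordered_strains(self) -> list[str]:
        return [self.strains[i] for i in self.leaf_order]


def _distance(data: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return pdist(data, metric="euclidean")
    if metric == "uncentered_correlation":
        norms = np.sqrt((data.astype(float) ** 2).sum(axis=1))
        if np.any(norms == 0):
            raise ScreenError(
                "all-zero profile: uncentered correlation undefined; use euclidean"
            )
        normed = data / norms[:, None]
        sim = normed @ normed.T
        d = 1.0 - sim
        np.fill_diagonal(d, 0.0)
        d[d < 0] = 0.0
        return squareform(d, checks=False)
    raise ScreenError(f"unknown metric {metric!r}")


def cluster_profiles(
    matrix: PhenotypeMatrix,
    metric: str = "euclidean",
    cluster_columns: bool = False,
) -> ClusterResult:
    """Complete-linkage hierarchical clustering of strain profiles.

    Euclidean distance on the ordinal codes by default; uncentered
    correlation (the historical default of the clustering program the field
    commonly pairs with TreeView) is selectable.  scipy's agglomeration is
    deterministic for a fixed input order, which fixes tie-breaking.
    """
    data = matrix.data.to_numpy(dtype=float)
    if data.shape[0] < 2:
        raise ScreenError("clustering needs at least 2 strains")
    Z = hierarchy.linkage(_distance(data, metric), method="complete")
    order = hierarchy.leaves_list(Z).tolist()
    col_Z = col_order = None
    if cluster_columns and data.shape[1] >= 2:
        col_Z = hierarchy.linkage(_distance(data.T, metric), method="complete")
        col_order = hierarchy.leaves_list(col_Z).tolist()
    return ClusterResult(
        linkage=Z, leaf_order=order, strains=matrix.strains, metric=metric,
        col_linkage=col_Z, col_leaf_order=col_order,
    )


# ---------------------------------------------------------------------------
# CDT / GTR / ATR export (clustered-data-table conventions)

def _tree_file_lines(Z: np.ndarray, item_prefix: str, node_prefix: str) -> list[str]:
    n = Z.shape[0] + 1
    lines = []
    for i, (a, b, height, _count) in enumerate(Z):
        a, b = int(a), int(b)
        na = f"{item_prefix}{a}X" if a < n else f"{node_prefix}{a - n + 1}X"
        nb = f"{item_prefix}{b}X" if b < n else f"{node_prefix}{b - n + 1}X"
        # joining value column: merge height (complete-linkage distance)
        lines.append(f"{node_prefix}{i + 1}X\t{na}\t{nb}\t{height:.6f}")
    return lines


def export_clustered(
    matrix: PhenotypeMatrix, result: ClusterResult, prefix: str | Path
) -> dict[str, Path]:
    """Write <prefix>.cdt and <prefix>.gtr (and .atr when columns clustered).

    The CDT holds the code matrix with rows in dendrogram leaf order; the
    GTR/ATR files hold the row/column join trees.  `parse_cdt` round-trips
    the matrix exactly.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gtr = prefix.with_suffix(".gtr")
    gtr.write_text("\n".join(_tree_file_lines(result.linkage, "GENE", "NODE")) + "\n")
    paths["gtr"] = gtr

    cols = matrix.conditions
    col_order = list(range(len(cols)))
    if result.col_linkage is not None:
        atr = prefix.with_suffix(".atr")
        atr.write_text("\n".join(_tree_file_lines(result.col_linkage, "ARRY", "NODE")) + "\n")
        paths["atr"] = atr
        col_order = result.col_leaf_order or col_order

    cdt_lines = []
    header = ["GID", "NAME", "GWEIGHT"] + [cols[j] for j in col_order]
    cdt_lines.append("\t".join(header))
    if result.col_linkage is not None:
        cdt_lines.append("\t".join(["AID", "", ""] + [f"ARRY{j}X" for j in col_order]))
    cdt_lines.append("\t".join(["EWEIGHT", "", ""] + ["1"] * len(cols)))
    for i in result.leaf_order:
        strain = result.strains[i]
        row = matrix.data.loc[strain]
        cdt_lines.append(
            "\t".join([f"GENE{i}X", strain, "1"] + [str(int(row.iloc[j])) for j in col_order])
        )
    cdt = prefix.with_suffix(".cdt")
    cdt.write_text("\n".join(cdt_lines) + "\n")
    paths["cdt"] = cdt
    return paths


def parse_cdt(path: str | Path) -> PhenotypeMatrix:
    """Re-import a CDT written by export_clustered (leaf order preserved)."""
    rows: list[tuple[str, list[int]]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        conditions = header[3:]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] in ("EWEIGHT", "AID"):
                continue
            rows.append((fields[1], [int(v) for v in fields[3:]]))
    data = pd.DataFrame(
        [v for _, v in rows], index=[s for s, _ in rows], columns=conditions
    )
    return PhenotypeMatrix(data=data)


def summarize(
    matrix: PhenotypeMatrix, denominator: int = 281, k_range: range = range(1, 6)
) -> dict:
    """JSON-ready summary: multi-stress counts for k=1..5 and the drug sets."""
    out: dict = {"schema": "delkit/1", "n_strains": len(matrix.strains),
                 "n_conditions": len(matrix.conditions), "denominator": denominator}
    for k in k_range:
        for mode in ("any_nonzero", "positive_only"):
            _, n, pct = count_multistress(matrix, k, mode=mode, denominator=denominator)
            out[f"k{k}_{mode}"] = {"count": n, "pct": round(pct, 2)}
    present = set(matrix.conditions)
    dna = [c for c in DNA_METABOLISM_CONDITIONS if c in present]
    if dna:
        out["dna_metabolism_sensitive"] = len(select_condition_set(matrix, dna))
    if set(ACTIN_CONDITIONS) <= present:
        out["latrunculin_A_sensitive"] = len(
            select_condition_set(matrix, list(ACTIN_CONDITIONS))
        )
    return out
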