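"""Pairwise divergence under pairwise deletion: p-distance and K2P.

For each sequence pair, sites where either member carries a gap, an N, or an
IUPAC ambiguity code are excluded (pairwise deletion). Over the remaining
``n_sites`` compared sites, ``P`` is the proportion of transition differences
(A<->G, C<->T) and ``Q`` the proportion of transversions. The raw p-distance
is ``P + Q``; the Kimura 2-parameter distance corrects for multiple hits:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

K2P is undefined (saturated) when ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``;
such pairs are reported, never clamped. The module also produces the
per-species-pair min/max divergence summary used for barcoding-gap analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from barcode_associate.records import MISSING, Dataset, encode_sequence

#: Intraspecific divergence above this value is flagged as unusually high
#: (the conventional 2% COI species-delineation threshold).
HIGH_INTRASPECIFIC_THRESHOLD = 0.02


class UndefinedPairError(ValueError):
    """Raised when two sequences share no unambiguous sites."""


class SaturationError(ValueError):
    """Raised when the K2P logarithm is undefined for a pair."""


@dataclass(frozen=True)
class PairComparison:
    """Site counts for one sequence pair after pairwise deletion."""

    n_sites: int
    P: float  # transition proportion
    Q: float  # transversion proportion

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise UndefinedPairError("no comparable sites after pairwise deletion")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError(f"invalid proportions P={self.P}, Q={self.Q}")


def compare_pair(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> PairComparison:
    """Count compared sites, transitions and transversions for one pair."""
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else seq_b
    if a.shape != b.shape:
        raise ValueError("sequences must be aligned to equal length")
    valid = (a != MISSING) & (b != MISSING)
    n = int(np.count_nonzero(valid))
    if n == 0:
        raise UndefinedPairError("no comparable sites after pairwise deletion")
    diff = valid & (a != b)
    # With codes A=0, C=1, G=2, T=3 the purines share parity bit 0, so a
    # difference is a transition exactly when the parity bits agree.
    ts = int(np.count_nonzero(diff & ((a & 1) == (b & 1))))
    tv = int(np.count_nonzero(diff)) - ts
    return PairComparison(n_sites=n, P=ts / n, Q=tv / n)


def p_distance(pc: PairComparison) -> float:
    """Raw proportion of differing sites, P + Q."""
    return pc.P + pc.Q


def k2p_distance(pc: PairComparison) -> float:
    """Kimura 2-parameter distance; raises :class:`SaturationError` when undefined."""
    w1 = 1.0 - 2.0 * pc.P - pc.Q
    w2 = 1.0 - 2.0 * pc.Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturation: K2P undefined for P={pc.P:.4f}, Q={pc.Q:.4f}"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # +0.0 normalizes -0.0


@dataclass
class DistanceMatrix:
    """Symmetric pairwise divergences with compared-site counts.

    Entries whose distance is undefined (zero overlap or K2P saturation) are
    NaN in ``d`` and listed in ``undefined`` with a reason.
    """

    ids: list[str]
    d: np.ndarray  # (n, n) float, NaN where undefined
    n: np.ndarray  # (n, n) int compared-site counts (0 where no overlap)
    model: str  # "p" or "k2p"
    undefined: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def distance(self, id_a: str, id_b: str) -> float:
        return float(self.d[self._index[id_a], self._index[id_b]])

    @property
    def is_fully_defined(self) -> bool:
        return not self.undefined

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = np.array([self._index[i] for i in ids])
        sub_undef = [
            (a, b, why) for (a, b, why) in self.undefined if a in ids and b in ids
        ]
        return DistanceMatrix(
            ids=list(ids),
            d=self.d[np.ix_(idx, idx)].copy(),
            n=self.n[np.ix_(idx, idx)].copy(),
            model=self.model,
            undefined=sub_undef,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_phylip(self) -> str:
        """PHYLIP square matrix (relaxed names)."""
        lines = [f"{len(self.ids)}"]
        for i, sid in enumerate(self.ids):
            row = " ".join(f"{v:.6f}" for v in np.nan_to_num(self.d[i], nan=-1.0))
            lines.append(f"{sid}  {row}")
        return "\n".join(lines) + "\n"

    def to_long(self) -> pd.DataFrame:
        """Long-form pair table: id_a, id_b, model, d, n_sites."""
        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                rows.append(
                    {
                        "id_a": self.ids[i],
                        "id_b": self.ids[j],
                        "model": self.model,
                        "d": self.d[i, j],
                        "n_sites": int(self.n[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _pairwise_counts(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (n_valid, P, Q) count matrices over all pairs."""
    m = len(X)
    valid = X != MISSING
    nmat = np.zeros((m, m), dtype=np.int64)
    ts = np.zeros((m, m), dtype=np.int64)
    tv = np.zeros((m, m), dtype=np.int64)
    parity = X & 1
    for i in range(m):
        both = valid[i] & valid[i + 1 :]
        diff = both & (X[i] != X[i + 1 :])
        same_parity = parity[i] == parity[i + 1 :]
        nmat[i, i + 1 :] = both.sum(axis=1)
        ts[i, i + 1 :] = (diff & same_parity).sum(axis=1)
        tv[i, i + 1 :] = diff.sum(axis=1) - ts[i, i + 1 :]
    nmat += nmat.T
    ts += ts.T
    tv += tv.T
    np.fill_diagonal(nmat, valid.sum(axis=1))
    return nmat, ts, tv


def build_matrix(ds: Dataset, model: str = "k2p") -> DistanceMatrix:
    """Compute the full pairwise distance matrix for a dataset."""
    if len(ds) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    return matrix_from_encoded(ds.encoded(), ds.ids, model)


def matrix_from_encoded(X: np.ndarray, ids: list[str], model: str = "k2p") -> DistanceMatrix:
    """Distance matrix from an already-encoded (n, L) uint8 alignment."""
    if model not in ("p", "k2p"):
        raise ValueError(f"unknown distance model {model!r}")
    nmat, ts, tv = _pairwise_counts(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(nmat > 0, ts / np.maximum(nmat, 1), np.nan)
        Q = np.where(nmat > 0, tv / np.maximum(nmat, 1), np.nan)

    undefined: list[tuple[str, str, str]] = []
    if model == "p":
        d = P + Q
    else:
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where((w1 > 0) & (w2 > 0), -0.5 * np.log(w1 * np.sqrt(np.abs(w2))) + 0.0, np.nan)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if nmat[i, j] > 0 and (w1[i, j] <= 0 or w2[i, j] <= 0):
                    undefined.append((ids[i], ids[j], "saturation"))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if nmat[i, j] == 0:
                undefined.append((ids[i], ids[j], "no_overlap"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=ids, d=d, n=nmat, model=model, undefined=undefined)


@dataclass
class DivergenceSummary:
    """Per-species-pair min/max divergence, barcoding-gap verdicts, flags.

    ``dmin``/``dmax`` are (n_species, n_species) matrices; the diagonal holds
    intraspecific ranges (NaN when a species has a single specimen).
    ``gap_verdict[s]`` is True when the species' maximum intraspecific
    divergence is below its minimum divergence to every other species.
    ``high_intraspecific[s]`` flags a maximum intraspecific divergence above
    the 2% threshold (a cryptic-species signal).
    """

    species: list[str]
    dmin: np.ndarray
    dmax: np.ndarray
    gap_verdict: dict[str, bool]
    high_intraspecific: dict[str, bool]
    intraspecific_threshold: float = HIGH_INTRASPECIFIC_THRESHOLD

    def pair_range(self, sp_a: str, sp_b: str) -> tuple[float, float]:
        i, j = self.species.index(sp_a), self.species.index(sp_b)
        return float(self.dmin[i, j]), float(self.dmax[i, j])

    def intraspecific_range(self, sp: str) -> tuple[float, float]:
        return self.pair_range(sp, sp)

    def has_gap(self, sp: str) -> bool:
        return self.gap_verdict[sp]

    def table(self, decimals: int = 2) -> pd.DataFrame:
        """Presentation table: 'min–max' strings rounded (default two decimals)."""
        cells = []
        for i in range(len(self.species)):
            row = {}
            for j in range(len(self.species)):
                lo, hi = self.dmin[i, j], self.dmax[i, j]
                row[self.species[j]] = (
                    ""
                    if np.isnan(lo)
                    else f"{round(lo, decimals):g}–{round(hi, decimals):g}"
                )
            cells.append(row)
        return pd.DataFrame(cells, index=self.species)


def summarize_divergence(
    dm: DistanceMatrix,
    labels: dict[str, str],
    intraspecific_threshold: float = HIGH_INTRASPECIFIC_THRESHOLD,
) -> DivergenceSummary:
    """Min/max divergence per species pair and barcoding-gap verdicts.

    ``labels`` maps specimen ID to species; UNKNOWN-labeled specimens are
    excluded. Verdicts are computed on unrounded values; rounding happens
    only in :meth:`DivergenceSummary.table`.
    """
    from barcode_associate.records import UNKNOWN

    species = sorted({s for s in labels.values() if s != UNKNOWN})
    members = {
        sp: [i for i, sid in enumerate(dm.ids) if labels.get(sid) == sp]
        for sp in species
    }
    k = len(species)
    dmin = np.full((k, k), np.nan)
    dmax = np.full((k, k), np.nan)
    for i, sa in enumerate(species):
        for j, sb in enumerate(species):
            if j < i:
                continue
            ia, ib = members[sa], members[sb]
            if i == j:
                if len(ia) < 2:
                    continue  # intraspecific range needs >= 2 specimens
                block = dm.d[np.ix_(ia, ia)]
                vals = block[np.triu_indices(len(ia), k=1)]
            else:
                vals = dm.d[np.ix_(ia, ib)].ravel()
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            dmin[i, j] = dmin[j, i] = vals.min()
            dmax[i, j] = dmax[j, i] = vals.max()

    gap_verdict: dict[str, bool] = {}
    high_intra: dict[str, bool] = {}
    for i, sp in enumerate(species):
        max_intra = dmax[i, i]
        inter_mins = np.array([dmin[i, j] for j in range(k) if j != i])
        inter_mins = inter_mins[~np.isnan(inter_mins)]
        if np.isnan(max_intra) or inter_mins.size == 0:
            # a single specimen cannot violate the gap; verdict defaults True
            gap_verdict[sp] = True
            high_intra[sp] = False
        else:
            gap_verdict[sp] = bool(max_intra < inter_mins.min())
            high_intra[sp] = bool(max_intra > intraspecific_threshold)
    return DivergenceSummary(
        species=species,
        dmin=dmin,
        dmax=dmax,
        gap_verdict=gap_verdict,
        high_intraspecific=high_intra,
        intraspecific_threshold=intraspecific_threshold,
    )
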