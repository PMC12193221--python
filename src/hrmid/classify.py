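"""Tm-panel species assignment with the 0.15 C decision rule.

An unknown sample's melt-peak signature is matched against a reference panel
of species-labelled peak Tm lists. Two peak Tms closer than the threshold
(default 0.15 C) are treated as indistinguishable; a separation of exactly
the threshold or more means distinct sequences. All comparisons happen after
rounding to the 0.01 C storage precision, with a 1e-9 guard against float
representation noise.

Every species within the threshold of the query is reported as a candidate:
one candidate is a ``match``, several are ``ambiguous`` (ambiguity is
surfaced, never resolved by panel order), none is ``novel``. In
``full_signature`` mode a candidate must also present the same number of
peaks, each matching within the threshold; otherwise the nearest species is
reported with status ``partial_signature``.

The core is the sklearn-style estimator :class:`TmPanelClassifier`
(``fit`` on a reference panel, ``predict`` on peak signatures); the
module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .meltcurve import PeakSet
from .records import PanelEntry, ReferencePanel

__all__ = [
    "TmPanelClassifier",
    "ClassificationResult",
    "BatchMismatchWarning",
    "classify",
    "pairwise_discriminability",
    "replicate_error",
    "batch_consistency_guard",
]

_EPS = 1e-9


class BatchMismatchWarning(UserWarning):
    """Query and panel come from different runs; Tm drift is possible."""


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of matching one query signature against a panel.

    ``candidates`` lists every (species, delta_tm) within the threshold,
    ascending by delta; ``delta_tm`` is the smallest candidate delta, or the
    distance to the nearest panel species when there is no candidate.
    """

    query_id: str
    status: str  # match | ambiguous | novel | partial_signature
    assigned_species: str | None
    delta_tm: float
    candidates: tuple[tuple[str, float], ...] = ()

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "status": self.status,
            "assigned_species": self.assigned_species,
            "delta_tm": self.delta_tm,
            "candidates": [list(c) for c in self.candidates],
        }


def _query_peaks(query) -> tuple[tuple[float, ...], float]:
    """Normalise a query to (all peak Tms, principal peak Tm)."""
    if isinstance(query, PeakSet):
        if len(query) == 0:
            raise ValueError("query has no peaks")
        return tuple(round(p.tm, 2) for p in query.peaks), round(query.principal.tm, 2)
    tms = tuple(round(float(t), 2) for t in np.atleast_1d(query))
    if not tms:
        raise ValueError("query has no peaks")
    # bare Tm lists carry no heights; take the first as principal
    return tms, tms[0]


class TmPanelClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-Tm species classifier over a reference melt-peak panel.

    Parameters
    ----------
    delta_tm_threshold : float
        Decision boundary in C. Peak separations strictly below it imply
        identity; at or above it, distinct sequences. Default 0.15.
    peak_match_mode : str
        ``"nearest_single"`` (default): candidates are species whose closest
        panel peak lies within the threshold of the query's principal peak.
        ``"full_signature"``: additionally requires equal peak counts with
        every sorted peak pair within the threshold.

    Attributes
    ----------
    panel_ : ReferencePanel
        The fitted reference panel.
    species_ : list of str
        Panel species names, in panel order.
    classes_ : ndarray of str
        Unique species labels (sklearn convention).
    """

    def __init__(self, delta_tm_threshold: float = 0.15,
                 peak_match_mode: str = "nearest_single"):
        self.delta_tm_threshold = delta_tm_threshold
        self.peak_match_mode = peak_match_mode

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None):
        """Fit on a :class:`ReferencePanel`, or on (peak lists, labels).

        ``X`` may be a ReferencePanel (``y`` ignored), or a sequence of
        per-species peak-Tm lists with ``y`` the species labels.
        """
        if self.delta_tm_threshold <= 0:
            raise ValueError("delta_tm_threshold must be > 0")
        if self.peak_match_mode not in ("nearest_single", "full_signature"):
            raise ValueError(
                f"unknown peak_match_mode {self.peak_match_mode!r}"
            )
        if isinstance(X, ReferencePanel):
            panel = X
        else:
            if y is None:
                raise ValueError("labels y are required when X is not a panel")
            entries = [
                PanelEntry(str(label), tuple(np.atleast_1d(peaks).astype(float)))
                for peaks, label in zip(X, y)
            ]
            panel = ReferencePanel(panel_id="fitted", primer_set="",
                                   entries=entries)
        if len(panel) == 0:
            # an empty panel is legal: every query comes back "novel"
            pass
        self.panel_ = panel
        self.species_ = panel.species
        self.classes_ = np.array(sorted(set(self.species_)))
        return self

    # -- prediction ---------------------------------------------------------

    def _classify_one(self, query, query_id: str = "query") -> ClassificationResult:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "panel_")
        peaks, principal = _query_peaks(query)
        thr = self.delta_tm_threshold

        if len(self.panel_) == 0:
            return ClassificationResult(query_id, "novel", None,
                                        float("inf"), ())

        nearest: list[tuple[str, float]] = []
        for entry in self.panel_.entries:
            delta = min(abs(principal - p) for p in entry.peaks)
            nearest.append((entry.species_name, round(delta, 2)))
        nearest.sort(key=lambda c: (c[1], c[0]))
        within = tuple(c for c in nearest if c[1] < thr - _EPS)

        if self.peak_match_mode == "full_signature":
            full: list[tuple[str, float]] = []
            for entry in self.panel_.entries:
                if len(entry.peaks) != len(peaks):
                    continue
                paired = zip(sorted(peaks), sorted(entry.peaks))
                sig_delta = max(abs(q - p) for q, p in paired)
                if sig_delta < thr - _EPS:
                    full.append((entry.species_name, round(sig_delta, 2)))
            full.sort(key=lambda c: (c[1], c[0]))
            if full:
                within = tuple(full)
            elif within:
                # principal peak matches a species, but the signatures have
                # different peak counts: report the nearest, flagged partial
                best = within[0]
                return ClassificationResult(
                    query_id, "partial_signature", best[0], best[1], within
                )
            else:
                within = ()

        if not within:
            return ClassificationResult(
                query_id, "novel", None, nearest[0][1], ()
            )
        if len(within) == 1:
            return ClassificationResult(
                query_id, "match", within[0][0], within[0][1], within
            )
        # several species within threshold; ties stay ambiguous
        return ClassificationResult(
            query_id, "ambiguous", None, within[0][1], within
        )

    def predict_result(self, X, query_ids=None) -> list[ClassificationResult]:
        """Full :class:`ClassificationResult` per query signature.

        ``X`` is a single PeakSet / peak-Tm list, or a sequence of them.
        """
        queries = X if isinstance(X, (list, tuple)) and not _is_single(X) else [X]
        ids = query_ids or [f"query_{i + 1}" for i in range(len(queries))]
        return [self._classify_one(q, qid) for q, qid in zip(queries, ids)]

    def predict(self, X):
        """Species label per query; ``None`` for novel/ambiguous queries."""
        return np.array(
            [r.assigned_species for r in self.predict_result(X)], dtype=object
        )


def _is_single(X) -> bool:
    """True if X looks like one query (scalars / one PeakSet) not a batch."""
    if isinstance(X, PeakSet):
        return True
    return all(np.isscalar(x) for x in X)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def classify(
    query,
    panel: ReferencePanel,
    delta_tm_threshold: float = 0.15,
    peak_match_mode: str = "nearest_single",
    query_id: str = "query",
) -> ClassificationResult:
    """Assign one query signature against a panel (estimator wrapper)."""
    clf = TmPanelClassifier(delta_tm_threshold, peak_match_mode).fit(panel)
    return clf._classify_one(query, query_id)


def pairwise_discriminability(
    panel: ReferencePanel, delta_tm_threshold: float = 0.15
) -> list[tuple[str, str]]:
    """Unordered species pairs whose principal peaks are indistinguishable.

    A pair is indistinguishable when its principal-peak separation is
    strictly below the threshold; a separation of exactly the threshold
    counts as distinct. The result is independent of species order.
    """
    if len(panel) < 2:
        raise ValueError("panel needs >= 2 species")
    pairs = []
    entries = panel.entries
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            delta = abs(entries[i].principal_peak - entries[j].principal_peak)
            if round(delta, 2) < delta_tm_threshold - _EPS:
                pair = tuple(sorted((entries[i].species_name,
                                     entries[j].species_name)))
                pairs.append(pair)
    return sorted(pairs)


@dataclass(frozen=True)
class ReplicateReport:
    """Per-species principal-peak drift between two runs of a panel."""

    per_species: dict[str, float]         # |delta Tm| per shared species
    shifts: dict[str, float] = field(default_factory=dict)  # signed b - a
    only_in_a: tuple[str, ...] = ()
    only_in_b: tuple[str, ...] = ()

    @property
    def min_error(self) -> float:
        return min(self.per_species.values())

    @property
    def max_error(self) -> float:
        return max(self.per_species.values())

    @property
    def n_upward(self) -> int:
        """How many shared species shifted to a higher Tm in the second run."""
        return sum(1 for v in self.shifts.values() if v > 0)


def replicate_error(panel_a: ReferencePanel,
                    panel_b: ReferencePanel) -> ReplicateReport:
    """Absolute principal-peak drift for species shared by two panels."""
    a = {e.species_name: e.principal_peak for e in panel_a.entries}
    b = {e.species_name: e.principal_peak for e in panel_b.entries}
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("panels share no species")
    per = {s: round(abs(b[s] - a[s]), 2) for s in shared}
    shifts = {s: round(b[s] - a[s], 2) for s in shared}
    return ReplicateReport(
        per_species=per,
        shifts=shifts,
        only_in_a=tuple(sorted(set(a) - set(b))),
        only_in_b=tuple(sorted(set(b) - set(a))),
    )


def batch_consistency_guard(query_batch: str | None,
                            panel_batch: str | None) -> str:
    """Warn when query and panel were not co-amplified in the same run.

    Tm values drift slightly between runs, so unknowns should be amplified
    simultaneously with the reference standards. Returns ``"pass"`` or a
    warning string (also emitted as a :class:`BatchMismatchWarning`);
    classification itself is never blocked.
    """
    if not query_batch or not panel_batch:
        msg = ("batch unknown: cannot verify that query and references were "
               "co-amplified; prefer running unknowns alongside the panel")
        warnings.warn(msg, BatchMismatchWarning, stacklevel=2)
        return msg
    if query_batch != panel_batch:
        msg = (f"query batch {query_batch!r} differs from panel batch "
               f"{panel_batch!r}: inter-run Tm drift is possible; co-amplify "
               f"references with unknowns")
        warnings.warn(msg, BatchMismatchWarning, stacklevel=2)
        return msg
    return "pass"
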