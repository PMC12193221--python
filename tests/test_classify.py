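"""Tm-panel classification, discriminability audit and replicate QC."""

import numpy as np
import pytest

from hrmid import (
    PanelEntry,
    ReferencePanel,
    TmPanelClassifier,
    batch_consistency_guard,
    classify,
    pairwise_discriminability,
    replicate_error,
)
from hrmid import panels
from hrmid.classify import BatchMismatchWarning


@pytest.fixture(scope="module")
def cox2():
    return panels.cox2_panel()


@pytest.fixture(scope="module")
def c1():
    return panels.c1_panel()


class TestClassify:
    def test_larva_unique_match(self):
        """The larval sample at 77.50 matches P. dux (77.40) uniquely."""
        r = classify([77.50], panels.cox2_larva_panel())
        assert r.status == "match"
        assert r.assigned_species == "P. dux"
        assert r.delta_tm == pytest.approx(0.10)
        assert len(r.candidates) == 1

    def test_adult_unknown_ambiguous_pair(self, cox2):
        """A query at 76.73 sits on B. peregrina exactly but H. ligurriens
        is only 0.03 C away: both are reported, ambiguity surfaced."""
        r = classify([76.73], cox2)
        assert r.status == "ambiguous"
        assert r.assigned_species is None
        assert r.candidates == (("B. peregrina", 0.0), ("H. ligurriens", 0.03))
        assert r.delta_tm == 0.0

    def test_single_peak_vs_multipeak_reference(self, c1):
        """A single-peak query near the first peak of the three-peak
        S. princeps signature is a partial-signature call."""
        r = classify([74.70], c1, peak_match_mode="full_signature")
        assert r.status == "partial_signature"
        assert r.assigned_species == "S. princeps"
        assert r.delta_tm == pytest.approx(0.05)

    def test_novel_query(self, cox2):
        r = classify([70.00], cox2)
        assert r.status == "novel"
        assert r.assigned_species is None
        assert r.candidates == ()

    def test_empty_panel_novel(self):
        empty = ReferencePanel("empty", "")
        r = classify([76.0], empty)
        assert r.status == "novel" and r.candidates == ()

    def test_boundary_exactly_at_threshold_is_distinct(self, cox2):
        """S. princeps (76.88) sits exactly 0.15 C from B. peregrina
        (76.73): at-threshold separations count as distinct species."""
        r = classify([76.88], cox2)
        names = [c[0] for c in r.candidates]
        assert "B. peregrina" not in names
        assert r.assigned_species == "S. princeps"

    def test_panel_order_invariance(self, cox2):
        shuffled = ReferencePanel(
            cox2.panel_id, cox2.primer_set, list(reversed(cox2.entries))
        )
        a = classify([76.73], cox2)
        b = classify([76.73], shuffled)
        assert a.status == b.status and a.candidates == b.candidates

    def test_threshold_monotonicity(self, cox2):
        """Enlarging the decision threshold never shrinks candidate sets."""
        prev = set()
        for thr in (0.05, 0.1, 0.15, 0.3, 0.6):
            r = classify([76.6], cox2, delta_tm_threshold=thr)
            names = {c[0] for c in r.candidates}
            assert prev <= names
            prev = names


class TestEstimatorApi:
    def test_fit_predict_on_peak_lists(self):
        X = [[75.0], [76.0], [77.0]]
        y = ["a", "b", "c"]
        clf = TmPanelClassifier().fit(X, y)
        assert list(clf.predict([[76.05], [74.95]])) == ["b", "a"]
        assert list(clf.classes_) == ["a", "b", "c"]

    def test_get_set_params_roundtrip(self):
        clf = TmPanelClassifier(delta_tm_threshold=0.2)
        params = clf.get_params()
        assert params["delta_tm_threshold"] == 0.2
        clf.set_params(peak_match_mode="full_signature")
        assert clf.peak_match_mode == "full_signature"

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        clf = TmPanelClassifier(delta_tm_threshold=0.1)
        assert clone(clf).delta_tm_threshold == 0.1

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            TmPanelClassifier().predict([[76.0]])

    def test_invalid_params_rejected_at_fit(self, cox2):
        with pytest.raises(ValueError):
            TmPanelClassifier(delta_tm_threshold=0.0).fit(cox2)
        with pytest.raises(ValueError):
            TmPanelClassifier(peak_match_mode="bogus").fit(cox2)


class TestDiscriminability:
    def test_cox2_panel_five_close_pairs(self, cox2):
        """Brute-force over all 45 pairs of the ten-species panel: exactly
        five principal-peak separations fall below 0.15 C."""
        pairs = pairwise_discriminability(cox2)
        assert len(pairs) == 5
        assert ("B. peregrina", "H. ligurriens") in pairs

    def test_c1_single_peak_species_one_pair(self, c1):
        singles = ReferencePanel(
            "c1s", c1.primer_set,
            [e for e in c1.entries if len(e.peaks) == 1],
        )
        pairs = pairwise_discriminability(singles)
        assert pairs == [("P. dux", "P. scopariiformis")]

    def test_at_threshold_pair_counts_as_distinct(self):
        panel = ReferencePanel("t", "", [PanelEntry("x", (76.73,)),
                                         PanelEntry("y", (76.88,))])
        assert pairwise_discriminability(panel) == []

    def test_reorder_invariance(self, cox2):
        shuffled = ReferencePanel(
            cox2.panel_id, cox2.primer_set, list(reversed(cox2.entries))
        )
        assert pairwise_discriminability(shuffled) == \
            pairwise_discriminability(cox2)


class TestReplicateError:
    def test_five_sarcophagidae_drift(self, cox2):
        """Repeat extraction shifts every shared species up by 0.02-0.10 C."""
        rep = replicate_error(cox2, panels.cox2_repeat_panel())
        assert rep.min_error == pytest.approx(0.02)
        assert rep.max_error == pytest.approx(0.10)
        assert len(rep.per_species) == 5
        assert rep.n_upward == 5

    def test_identical_panels_zero(self, cox2):
        rep = replicate_error(cox2, cox2)
        assert set(rep.per_species.values()) == {0.0}

    def test_disjoint_panels_error(self, cox2):
        other = ReferencePanel("o", "", [PanelEntry("nobody", (75.0,))])
        with pytest.raises(ValueError):
            replicate_error(cox2, other)


class TestBatchGuard:
    def test_same_batch_passes(self):
        assert batch_consistency_guard("run1", "run1") == "pass"

    def test_differing_batches_warn(self):
        with pytest.warns(BatchMismatchWarning):
            msg = batch_consistency_guard("run1", "run2")
        assert "drift" in msg

    def test_missing_batch_warns_unknown(self):
        with pytest.warns(BatchMismatchWarning):
            msg = batch_consistency_guard(None, "run1")
        assert "batch unknown" in msg


def test_end_to_end_synthetic_identification():
    """A 10-species panel with principal Tms spaced >= 0.3 C: simulated
    query curves at low noise classify to the right species every time
    (200 seeded trials)."""
    from hrmid import MeltConfig, call_peaks, derivative_curve, simulate_melt

    tms = [74.0 + 0.4 * i for i in range(10)]
    panel = ReferencePanel(
        "synth", "synth",
        [PanelEntry(f"sp{i}", (tm,)) for i, tm in enumerate(tms)],
    )
    clf = TmPanelClassifier().fit(panel)
    rng = np.random.default_rng(7)
    correct = 0
    for trial in range(200):
        true_idx = int(rng.integers(0, 10))
        cfg = MeltConfig(noise_sd=0.002, seed=trial)
        curve = simulate_melt([(tms[true_idx], 1.0)], cfg)
        ps = call_peaks(derivative_curve(curve))
        result = clf._classify_one(ps, f"trial_{trial}")
        if (result.status == "match"
                and result.assigned_species == f"sp{true_idx}"):
            correct += 1
    assert correct == 200
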