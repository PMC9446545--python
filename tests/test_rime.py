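"""RIME interactor filtering and three-set Venn region counts."""

from itertools import combinations

import pandas as pd
import pytest

from zcwcross import RimeThresholds, filter_evidence, replicate_venn
from zcwcross.rime import read_evidence
from zcwcross.simulate import make_rime_table


def row(pid, rep="Rep1", antibody="target", batch=None, score=25.0, unique=2, spectra=6):
    return {
        "protein_id": pid,
        "replicate": rep,
        "antibody": antibody,
        "batch": batch or rep,
        "neg10lgP": score,
        "unique_peptides": unique,
        "spectral_counts": spectra,
    }


def frame(*rows):
    return pd.DataFrame(list(rows))


class TestFilter:
    def test_all_criteria_met_is_positive(self):
        positives = filter_evidence(frame(row("P1")))
        assert positives["Rep1"] == {"P1"}

    def test_score_boundary_is_inclusive_at_20(self):
        positives = filter_evidence(frame(row("P1", score=20.0), row("P2", score=19.9)))
        assert positives["Rep1"] == {"P1"}

    def test_spectra_boundary_is_inclusive_at_5(self):
        positives = filter_evidence(frame(row("P1", spectra=5), row("P2", spectra=4)))
        assert positives["Rep1"] == {"P1"}

    def test_igg_hit_excludes_regardless_of_scores(self):
        positives = filter_evidence(
            frame(
                row("P1", score=60.0, unique=9, spectra=50),
                row("P1", antibody="IgG", score=5.0, unique=1, spectra=1),
            )
        )
        assert positives["Rep1"] == set()

    def test_igg_exclusion_is_batch_matched(self):
        positives = filter_evidence(
            frame(
                row("P1", rep="Rep1", batch="B1"),
                row("P1", rep="Rep2", batch="B2"),
                row("P1", antibody="IgG", rep="Rep1", batch="B1"),
            )
        )
        assert positives["Rep1"] == set()
        assert positives["Rep2"] == {"P1"}  # different batch: unaffected

    def test_igg_exclusion_idempotent_and_order_independent(self):
        rows = [
            row("P1"),
            row("P1", antibody="IgG"),
            row("P2"),
        ]
        forward = filter_evidence(frame(*rows))
        backward = filter_evidence(frame(*rows[::-1]))
        doubled = filter_evidence(frame(*rows, row("P1", antibody="IgG")))
        assert forward == backward == doubled

    def test_thresholds_monotone(self):
        table, _ = make_rime_table(n_true_interactors=40, n_background=40, seed=3)
        base = filter_evidence(table)
        for tighter in (
            RimeThresholds(min_neg10lgP=30),
            RimeThresholds(min_unique_peptides=3),
            RimeThresholds(min_spectral_counts=10),
        ):
            strict = filter_evidence(table, tighter)
            for rep in base:
                assert strict.get(rep, set()) <= base[rep]

    def test_unknown_antibody_label_rejected(self):
        with pytest.raises(ValueError, match="antibody"):
            filter_evidence(frame(row("P1", antibody="mock")))


class TestVenn:
    def test_identical_sets(self):
        s = {"Rep1": {"a", "b"}, "Rep2": {"a", "b"}, "Rep3": {"a", "b"}}
        venn = replicate_venn(s)
        assert venn["Rep1&Rep2&Rep3"] == 2
        assert venn["union"] == 2
        assert sum(v for k, v in venn.items() if k != "union") == 2

    def test_pairwise_disjoint_sets_add_up(self):
        s = {"Rep1": {1, 2, 3}, "Rep2": {4, 5, 6, 7}, "Rep3": {8, 9, 10, 11, 12}}
        venn = replicate_venn(s)
        assert venn["union"] == 12
        assert venn["Rep1"] == 3 and venn["Rep2"] == 4 and venn["Rep3"] == 5
        assert venn["Rep1&Rep2"] == 0

    def test_random_memberships_match_enumeration(self, rng):
        names = ("Rep1", "Rep2", "Rep3")
        proteins = [f"P{i}" for i in range(50)]
        sets = {n: set() for n in names}
        membership = {}
        for p in proteins:
            m = tuple(n for n in names if rng.random() < 0.5)
            membership[p] = m
            for n in m:
                sets[n].add(p)
        venn = replicate_venn(sets)
        # brute-force: count proteins per exact membership pattern
        for k in (1, 2, 3):
            for combo in combinations(names, k):
                expected = sum(1 for p in proteins if membership[p] == combo)
                assert venn["&".join(combo)] == expected
        assert venn["union"] == sum(1 for p in proteins if membership[p])
        assert sum(v for key, v in venn.items() if key != "union") == venn["union"]


def test_read_evidence_column_mapping(tmp_path):
    df = pd.DataFrame(
        {
            "Accession": ["P1"],
            "Sample": ["Rep1"],
            "Ab": ["target"],
            "Batch": ["B1"],
            "-10lgP": [33.0],
            "#Unique": [2],
            "#Spec": [9],
        }
    )
    path = tmp_path / "ev.tsv"
    df.to_csv(path, sep="\t", index=False)
    parsed = read_evidence(
        path,
        columns={
            "protein_id": "Accession",
            "replicate": "Sample",
            "antibody": "Ab",
            "batch": "Batch",
            "neg10lgP": "-10lgP",
            "unique_peptides": "#Unique",
            "spectral_counts": "#Spec",
        },
    )
    assert filter_evidence(parsed)["Rep1"] == {"P1"}


class TestSyntheticRime:
    def test_clean_table_recovers_exact_truth(self):
        table, truth = make_rime_table(n_true_interactors=30, n_background=30,
                                       contamination_rate=0.0, seed=11)
        union = set().union(*filter_evidence(table).values())
        assert union == truth

    def test_all_igg_means_zero_positives(self):
        table, _ = make_rime_table(n_true_interactors=10, n_background=0, seed=2)
        igg = table.assign(antibody="IgG")
        both = pd.concat([table, igg], ignore_index=True)
        assert set().union(*filter_evidence(both).values()) == set()

    def test_filter_matches_rowwise_oracle(self):
        """200 proteins: the vectorized filter equals a per-row re-check."""
        table, _ = make_rime_table(n_true_interactors=100, n_background=100, seed=7)
        got = filter_evidence(table)
        igg_hits = {
            (r.batch, r.protein_id)
            for r in table.itertuples(index=False)
            if r.antibody == "IgG"
        }
        expected: dict[str, set] = {rep: set() for rep in got}
        for r in table.itertuples(index=False):
            if (
                r.antibody == "target"
                and r.neg10lgP >= 20
                and r.unique_peptides >= 1
                and r.spectral_counts >= 5
                and (r.batch, r.protein_id) not in igg_hits
            ):
                expected.setdefault(r.replicate, set()).add(r.protein_id)
        assert got == expected
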