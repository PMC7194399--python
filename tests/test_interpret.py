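"""Richness, domain overview, cladogram summaries and correlations."""

import numpy as np
import pandas as pd
import pytest

from microcca import (
    AbundanceMatrix,
    ValidationError,
    clade_summary,
    correlate,
    correlation_report,
    export_cladogram,
    richness,
    traditional_overview,
)
from microcca.cca import CcaModel, SelectionResult
from microcca.io_formats import RANKS, TaxonomyTable


def make_taxonomy(entries: dict[str, str]) -> TaxonomyTable:
    rows = {}
    for otu, lineage in entries.items():
        names = lineage.split(";")
        names += ["unknown"] * (len(RANKS) - len(names))
        rows[otu] = names
    return TaxonomyTable(
        lineages=pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    )


def make_model(loadings: dict[str, list[float]]) -> CcaModel:
    df = pd.DataFrame(loadings).T
    df.columns = [f"CC{i + 1}" for i in range(df.shape[1])]
    k = df.shape[1]
    return CcaModel(
        scores=pd.DataFrame(np.zeros((3, k)), columns=df.columns),
        loadings=df,
        saliences=df.abs() / df.abs().sum(),
        explained=pd.Series(np.zeros(k), index=df.columns),
        iterations=pd.Series(np.ones(k, dtype=int), index=df.columns),
        converged=pd.Series(True, index=df.columns),
        tol=1e-10,
        max_iter=500,
    )


def make_selection(per_component: dict[int, list[str]]) -> SelectionResult:
    tables = {}
    for c, otus in per_component.items():
        tables[c] = pd.DataFrame(
            {
                "otu_id": otus,
                "covariance": np.ones(len(otus)),
                "correlation": np.ones(len(otus)),
                "sign": np.ones(len(otus), dtype=int),
            }
        )
    return SelectionResult(tables=tables, thresholds=dict.fromkeys(per_component, 0.0))


class TestRichness:
    def test_counts_nonzero_restricted(self):
        values = pd.DataFrame(
            [[0.5, 0.5, 0.0], [0.2, 0.0, 0.8]],
            index=["s1", "s2"],
            columns=["a", "b", "c"],
        )
        abund = AbundanceMatrix(values=values)
        r = richness(abund, restrict_to=["a", "b", "c"])
        assert r.tolist() == [2, 2]
        assert richness(abund, restrict_to=["a", "b"]).tolist() == [2, 1]

    def test_all_nonzero_equals_restriction_size(self):
        values = pd.DataFrame(np.full((3, 4), 0.25))
        abund = AbundanceMatrix(values=values)
        assert richness(abund).tolist() == [4, 4, 4]

    def test_matches_brute_force(self, fitted):
        abund = fitted["abund"]
        ubiq = fitted["part"].ubiquitous
        r = richness(abund, restrict_to=ubiq)
        arr = abund.values.loc[:, ubiq].to_numpy()
        for i, sid in enumerate(abund.sample_ids):
            assert r[sid] == int((arr[i] > 0).sum())


class TestTraditionalOverview:
    @pytest.fixture
    def small(self):
        # 2 samples; archaeal otu_a always dominant, otu_b sub-threshold,
        # bacterial otu_c above threshold in one sample only
        values = pd.DataFrame(
            {
                "otu_a": [0.60, 0.591],
                "otu_b": [0.009, 0.009],
                "otu_c": [0.011, 0.0],
                "otu_d": [0.38, 0.40],
            },
            index=["s1", "s2"],
        )
        tax = make_taxonomy(
            {
                "otu_a": "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosarcinaceae;Methanosarcina",
                "otu_b": "Archaea;Euryarchaeota;Methanomicrobia;Methanomicrobiales;Methanomicrobiaceae;Methanoculleus",
                "otu_c": "Bacteria;Firmicutes;Clostridia;Clostridiales;Clostridiaceae;Clostridium",
                "otu_d": "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Marinilabiliaceae;Alkaliflexus",
            }
        )
        return AbundanceMatrix(values=values), tax

    def test_threshold_rules(self, small):
        abund, tax = small
        out = traditional_overview(abund, tax, threshold=0.01)
        arch = out["Archaea"]
        assert "otu_a" in arch.table.index          # dominant, kept
        assert "otu_b" not in arch.table.index      # 0.9 % max -> pooled
        assert arch.table.loc["Other Archaea", "s1"] == pytest.approx(0.009)
        bact = out["Bacteria"]
        assert "otu_c" in bact.table.index          # 1.1 % in one sample suffices

    def test_display_rank_labels(self, small):
        abund, tax = small
        out = traditional_overview(abund, tax)
        assert out["Archaea"].labels["otu_a"] == "Methanosarcina"   # genus
        assert out["Bacteria"].labels["otu_d"] == "Bacteroidales"   # order

    def test_conservation_per_domain(self, fitted, synth_data):
        abund = fitted["abund"]
        out = traditional_overview(abund, synth_data.taxonomy)
        domains = synth_data.taxonomy.lineages.loc[abund.otu_ids, "domain"]
        for domain in ("Archaea", "Bacteria"):
            members = [o for o, d in domains.items() if d == domain]
            expected = abund.values.loc[:, members].sum(axis=1)
            got = out[domain].table.sum(axis=0)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_unknown_domain_routed_and_flagged(self, small, caplog):
        import logging

        abund, tax = small
        tax.lineages.loc["otu_d", "domain"] = "Eukaryota"
        with caplog.at_level(logging.WARNING, logger="microcca.interpret"):
            out = traditional_overview(abund, tax)
        assert "unclassified domain" in out
        np.testing.assert_allclose(
            out["unclassified domain"].table.loc["unclassified domain"],
            abund.values["otu_d"],
        )


class TestCladeSummary:
    @pytest.fixture
    def setup(self):
        tax = make_taxonomy(
            {
                "otu_1": "Bacteria;Firmicutes;Clostridia;Clostridiales;Clostridiaceae;Clostridium",
                "otu_2": "Bacteria;Firmicutes;Clostridia;Clostridiales;Clostridiaceae;Clostridium",
                "otu_3": "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosarcinaceae;Methanosarcina",
            }
        )
        model = make_model(
            {"otu_1": [0.3, 0.1], "otu_2": [-0.1, 0.2], "otu_3": [0.5, -0.4]}
        )
        selection = make_selection({1: ["otu_1", "otu_2"], 2: ["otu_3"]})
        return tax, model, selection

    def test_sibling_mean(self, setup):
        tax, model, selection = setup
        summaries = clade_summary(selection, model, tax)
        cc1 = summaries[0]
        family = ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae")
        assert cc1.node_means[family] == pytest.approx((0.3 - 0.1) / 2)

    def test_single_leaf_clade_mean_equals_leaf(self, setup):
        tax, model, selection = setup
        cc2 = clade_summary(selection, model, tax)[1]
        arch = ("Archaea",)
        assert cc2.node_means[arch] == pytest.approx(-0.4)

    def test_layout_shared_and_unselected_blank(self, setup):
        tax, model, selection = setup
        summaries = clade_summary(selection, model, tax)
        leaves0 = [l.otu_id for l in summaries[0].root.leaves()]
        leaves1 = [l.otu_id for l in summaries[1].root.leaves()]
        assert leaves0 == leaves1  # same tree for every component
        assert np.isnan(summaries[0].leaf_values["otu_3"])  # not selected in CC1
        assert np.isnan(summaries[1].leaf_values["otu_1"])

    def test_node_means_match_brute_force(self, fitted, synth_data):
        summaries = clade_summary(fitted["selection"], fitted["model"], synth_data.taxonomy)
        cs = summaries[0]
        lineages = synth_data.taxonomy.lineages
        for path, mean in cs.node_means.items():
            members = [
                otu
                for otu in cs.leaf_values.index
                if tuple(lineages.loc[otu, list(RANKS)])[: len(path)] == path
                and not np.isnan(cs.leaf_values[otu])
            ]
            if not members:
                assert np.isnan(mean)
            else:
                assert mean == pytest.approx(
                    float(np.mean([cs.leaf_values[o] for o in members]))
                )

    def test_missing_taxonomy_goes_under_unknown_chain(self, setup):
        tax, model, _ = setup
        model.loadings.loc["otu_x"] = [0.2, 0.0]
        selection = make_selection({1: ["otu_1", "otu_x"], 2: []})
        cs = clade_summary(selection, model, tax)[0]
        assert "otu_x" in [l.otu_id for l in cs.root.leaves()]
        chain = ("unknown",) * len(RANKS)
        assert chain in cs.node_means


class TestExportCladogram:
    def test_newick_round_trip_and_annotation_rows(self, tmp_path, setup_export):
        cs, n_leaves = setup_export
        nwk, annot = export_cladogram(cs, tmp_path)
        import dendropy

        tree = dendropy.Tree.get(path=str(nwk), schema="newick")
        assert len(tree.leaf_nodes()) == n_leaves
        rows = [l.split("\t") for l in annot.read_text().strip().split("\n")]
        shaded = sum(1 for m in cs.node_means.values() if not np.isnan(m))
        assert len(rows) == n_leaves + shaded
        assert all(len(r) == 3 for r in rows)

    def test_negative_loading_gets_negative_color(self, tmp_path, setup_export):
        cs, _ = setup_export
        _, annot = export_cladogram(cs, tmp_path)
        rows = dict(
            (r.split("\t")[0], r.split("\t")[2]) for r in annot.read_text().strip().split("\n")
            if r.split("\t")[1] == "clade_marker_color"
        )
        assert rows["otu_2"].startswith("#00ffff")  # negative loading -> cyan
        assert rows["otu_1"].startswith("#ff0000")

    @pytest.fixture
    def setup_export(self):
        tax = make_taxonomy(
            {
                "otu_1": "Bacteria;Firmicutes;Clostridia;Clostridiales;Clostridiaceae;Clostridium",
                "otu_2": "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae;Ruminococcus",
                "otu_3": "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosarcinaceae;Methanosarcina",
            }
        )
        model = make_model(
            {"otu_1": [0.3, 0.0], "otu_2": [-0.1, 0.0], "otu_3": [0.5, 0.0]}
        )
        selection = make_selection({1: ["otu_1", "otu_2", "otu_3"]})
        cs = clade_summary(selection, model, tax)[0]
        return cs, 3


class TestCorrelate:
    def test_self_and_negated(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert correlate(x, x) == (pytest.approx(1.0), 4)
        assert correlate(x, -x) == (pytest.approx(-1.0), 4)

    def test_orthogonal_centered(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        r, n = correlate(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_two_pass_formula(self):
        rng = np.random.default_rng(21)
        x, y = rng.normal(size=(2, 30))
        r, n = correlate(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert r == pytest.approx(expected, abs=1e-12)
        assert n == 30

    def test_pairwise_complete_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
        r, n = correlate(x, y)
        assert n == 3
        assert r == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError, match="pairs"):
            correlate([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValidationError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCorrelationReport:
    def test_exact_linear_marker(self, fitted, synth_data):
        """A marker that is an exact affine image of the CC1 scores yields
        |r| = 1."""
        from microcca.io_formats import PerformanceTable

        model = fitted["model"]
        exact = PerformanceTable(
            values=pd.DataFrame(
                {"exact": 2.0 * model.scores["CC1"] + 1.0,
                 "flat": np.ones(len(model.sample_ids))},
                index=model.scores.index,
            )
        )
        report = correlation_report(
            model, fitted["abund"], synth_data.taxonomy, synth_data.metadata, exact,
            ubiquitous=fitted["part"].ubiquitous,
        )
        assert abs(report.r("CC1", "exact")) == pytest.approx(1.0, abs=1e-10)
        flat_row = report.table[
            (report.table["series"] == "CC1") & (report.table["target"] == "flat")
        ]
        assert flat_row["error"].iloc[0] != ""  # zero-variance marker -> error cell

    def test_planted_coupling_signs_recovered(self):
        """Across seeds, the sign pattern of score-marker correlations
        matches the planted couplings (up to the component's arbitrary
        orientation, fixed by the gradient)."""
        from scipy import stats

        from microcca import (
            fit_cca,
            pareto_scale,
            prevalence_partition,
            total_sum_scale,
        )
        from microcca.synthetic import SyntheticScenario, generate

        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            data = generate(SyntheticScenario(seed=seed))
            abund = total_sum_scale(data.otu_table)
            part = prevalence_partition(abund)
            model = fit_cca(pareto_scale(abund, part.ubiquitous))
            t = model.scores["CC1"].to_numpy()
            orient = np.sign(stats.pearsonr(t, data.truth.gradient.to_numpy())[0])
            good = True
            for cpl in data.truth.marker_couplings:
                if cpl.latent != "gradient":
                    continue
                r = stats.pearsonr(t, data.markers.values[cpl.name].to_numpy())[0]
                good &= np.sign(r) == orient * np.sign(cpl.slope)
            ok += good
        assert ok == n_seeds

    def test_invariant_to_consistent_sample_reordering(self, fitted, synth_data):
        model = fitted["model"]
        report_a = correlation_report(
            model, fitted["abund"], synth_data.taxonomy, synth_data.metadata,
            synth_data.markers, ubiquitous=fitted["part"].ubiquitous,
        )
        # reorder every sample-indexed input consistently
        perm = np.random.default_rng(0).permutation(model.sample_ids)
        from dataclasses import replace

        model_p = replace(model, scores=model.scores.loc[perm])
        abund_p = AbundanceMatrix(values=fitted["abund"].values.loc[perm])
        from microcca.io_formats import PerformanceTable, SampleMetadata

        meta_p = SampleMetadata(table=synth_data.metadata.table.loc[perm])
        markers_p = PerformanceTable(values=synth_data.markers.values.loc[perm])
        report_b = correlation_report(
            model_p, abund_p, synth_data.taxonomy, meta_p, markers_p,
            ubiquitous=fitted["part"].ubiquitous,
        )
        pd.testing.assert_frame_equal(report_a.table, report_b.table)
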