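"""LP core: FBA, FVA, knockouts, parsimonious FBA, six-way classification."""

import numpy as np
import pytest

from vinoflux.pfba import (
    CATEGORIES,
    classify_reactions,
    fba,
    fva,
    pfba,
    single_reaction_deletions,
)
from vinoflux.synthetic import _model_from_rows, generate_toy_network, oracle_classify


@pytest.fixture
def chain():
    model, _ = generate_toy_network("chain", size=3)
    return model


@pytest.fixture
def parallel():
    model, _ = generate_toy_network("parallel_equal_yield")
    return model


class TestFBA:
    def test_chain_growth_equals_uptake_bound(self, chain):
        sol = fba(chain)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
        assert np.abs(chain.S @ sol.v).max() <= 1e-9

    def test_internal_bottleneck(self, chain):
        j = chain.rxn_index("R2")
        chain.ub[j] = 4.0
        assert fba(chain).objective_value == pytest.approx(4.0, abs=1e-9)

    def test_matches_cobra_oracle(self):
        cobra = pytest.importorskip("cobra")
        for seed in range(5):
            model, _ = generate_toy_network("random", size=8, seed=seed)
            cm = cobra.Model("t")
            mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolites}
            rxns = []
            for j, rid in enumerate(model.reactions):
                r = cobra.Reaction(rid, lower_bound=model.lb[j],
                                   upper_bound=model.ub[j])
                r.add_metabolites(
                    {mets[m]: model.S[i, j]
                     for i, m in enumerate(model.metabolites)
                     if model.S[i, j] != 0}
                )
                rxns.append(r)
            cm.add_reactions(rxns)
            cm.objective = model.biomass_rxn
            assert fba(model).objective_value == pytest.approx(
                cm.slim_optimize(), abs=1e-9
            )

    def test_infeasible_reported(self, chain):
        j = chain.rxn_index("EX_M0")
        chain.lb[j] = chain.ub[j] = 0.0
        chain.lb[chain.rxn_index("BIOMASS")] = 1.0
        assert fba(chain).status == "infeasible"


class TestFVA:
    def test_chain_fully_coupled_at_optimum(self, chain):
        ranges = fva(chain, fraction_of_optimum=1.0)
        for r in ("R1", "R2", "R3", "BIOMASS"):
            lo, hi = ranges[r]
            assert lo == pytest.approx(10.0, abs=1e-6)
            assert hi == pytest.approx(10.0, abs=1e-6)

    def test_parallel_paths_each_optional(self, parallel):
        ranges = fva(parallel, fraction_of_optimum=1.0)
        for r in ("SHORT", "LONG1"):
            lo, hi = ranges[r]
            assert lo == pytest.approx(0.0, abs=1e-6)
            assert hi == pytest.approx(10.0, abs=1e-6)

    def test_orphan_reaction_pinned_to_zero(self):
        model, _ = generate_toy_network("suboptimal_branch")
        assert fva(model, 0.0, reactions=["ORPHAN"])["ORPHAN"] == (0.0, 0.0)


class TestDeletions:
    def test_chain_all_essential(self, chain):
        _, essential = single_reaction_deletions(chain)
        assert essential == set(chain.reactions)

    def test_parallel_paths_not_essential(self, parallel):
        growth, essential = single_reaction_deletions(parallel)
        assert essential == {"EX_A", "BIOMASS"}
        assert growth["SHORT"] == pytest.approx(10.0, abs=1e-6)


class TestPFBA:
    def test_chain_total_flux_is_forced_sum(self, chain):
        sol = pfba(chain)
        # three gene-associated reactions each carrying 10
        assert sol.total_gene_flux == pytest.approx(30.0, abs=1e-6)
        # growth is refixed with a 1e-9 relative slack in stage 2
        assert sol.objective_value == pytest.approx(10.0, rel=1e-8)

    def test_short_path_preferred(self, parallel):
        sol = pfba(parallel)
        assert sol.flux(parallel, "SHORT") == pytest.approx(10.0, abs=1e-6)
        assert sol.flux(parallel, "LONG1") == pytest.approx(0.0, abs=1e-6)

    def test_total_flux_not_above_random_optimal_vertices(self, parallel):
        sol = pfba(parallel)
        rng = np.random.default_rng(0)
        opt = fba(parallel).objective_value
        n = len(parallel.reactions)
        gene = parallel.gene_associated
        for _ in range(100):
            # random objective over the optimal face
            c = rng.normal(size=n)
            probe = parallel.copy()
            jb = probe.rxn_index(probe.biomass_rxn)
            probe.lb[jb] = opt * (1 - 1e-9)
            from vinoflux._lp import solve_lp

            res = solve_lp(c, probe.S, np.zeros(probe.S.shape[0]),
                           probe.lb, probe.ub)
            if res.ok:
                assert sol.total_gene_flux <= np.abs(
                    res.x[gene]
                ).sum() + 1e-6

    def test_non_gene_reactions_excluded_from_objective(self):
        # two equal-yield routes: A->B direct (two NON-gene steps via C) vs
        # one gene step; minimizing gene flux must pick the longer non-gene
        # route, whereas an all-reaction objective would pick the short one
        rows = [
            ("EX_A", "A ->", -10.0, 1000.0, False, "exchange"),
            ("GENE1", "A -> B", 0.0, 1000.0, True, "short"),
            ("SPON1", "A -> C", 0.0, 1000.0, False, "long"),
            ("SPON2", "C -> B", 0.0, 1000.0, False, "long"),
            ("BIOMASS", "B ->", 0.0, 1000.0, False, "biomass"),
        ]
        model = _model_from_rows(rows, "BIOMASS")
        sol = pfba(model)
        assert sol.flux(model, "SPON1") == pytest.approx(10.0, abs=1e-6)
        assert sol.flux(model, "GENE1") == pytest.approx(0.0, abs=1e-6)
        assert sol.total_gene_flux == pytest.approx(0.0, abs=1e-6)


EXPECTED_CLASSES = {
    # frozen from the construction of each template (single path forced;
    # equal-yield routes; growth-costing branch; Ehrlich chain coupling)
    "chain": {
        "EX_M0": "essential", "R1": "essential", "R2": "essential",
        "R3": "essential", "BIOMASS": "essential",
    },
    "parallel_equal_yield": {
        "EX_A": "essential", "SHORT": "pfba_optima",
        "LONG1": "ELE", "LONG2": "ELE", "BIOMASS": "essential",
    },
    "suboptimal_branch": {
        "EX_A": "essential", "R1": "essential", "DIVERT": "MLE",
        "EX_D": "MLE", "EX_E": "no_flux", "R3": "no_flux",
        "ORPHAN": "blocked", "BIOMASS": "essential",
    },
    "ehrlich_motif": {
        "EX_glucose": "essential", "EX_Leu": "essential", "LEUt": "essential",
        "GLYC": "essential", "AKGS": "essential", "TA": "essential",
        "KADC": "essential", "ALR": "essential", "ACS": "ELE", "ATF": "ELE",
        "FERM": "ELE", "EX_EtOH": "ELE", "EX_FOL": "pfba_optima",
        "EX_EST": "ELE", "BIOMASS": "essential",
    },
}


class TestClassification:
    @pytest.mark.parametrize("template", sorted(EXPECTED_CLASSES))
    def test_templates_match_frozen_expectations(self, template):
        model, truth = generate_toy_network(template, size=3)
        cls = classify_reactions(model)
        assert cls.category == EXPECTED_CLASSES[template]
        assert truth.reaction_classes == EXPECTED_CLASSES[template]

    @pytest.mark.parametrize("seed", range(6))
    def test_random_models_match_oracle(self, seed):
        model, truth = generate_toy_network("random", size=10, seed=seed)
        cls = classify_reactions(model)
        assert cls.category == truth.reaction_classes

    def test_partition_property(self):
        model, _ = generate_toy_network("suboptimal_branch")
        cls = classify_reactions(model)
        assert set(cls.category) == set(model.reactions)
        assert all(c in CATEGORIES for c in cls.category.values())
        assert cls.reactions_in("essential") & cls.reactions_in("blocked") == set()

    @pytest.mark.parametrize("tol", [1e-10, 1e-9, 1e-8])
    def test_flux_threshold_invariance(self, tol):
        for template in ("parallel_equal_yield", "suboptimal_branch",
                         "ehrlich_motif"):
            model, _ = generate_toy_network(template)
            cls = classify_reactions(model, flux_tol=tol)
            assert cls.category == EXPECTED_CLASSES[template]

    def test_essential_subset_of_always_active(self):
        model, _ = generate_toy_network("ehrlich_motif")
        cls = classify_reactions(model)
        ranges = fva(model, fraction_of_optimum=1.0)
        for r in cls.reactions_in("essential"):
            lo, hi = ranges[r]
            assert lo > 1e-6 or hi < -1e-6, f"{r} inactive at optimum"

    def test_oracle_agrees_on_named_templates(self):
        for template in EXPECTED_CLASSES:
            model, _ = generate_toy_network(template, size=3)
            assert oracle_classify(model) == EXPECTED_CLASSES[template]
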