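import itertools
import math

import numpy as np
import pytest

from hbcube.errors import (
    InvalidSitesError,
    InvalidSiteStateError,
    MissingDataError,
    SizeLimitError,
)
from hbcube.landscape import (
    Genotype,
    GenotypePhenotypeTable,
    SiteDef,
    double_mutant_cycle,
    effects_on_all_backgrounds,
    enumerate_genotypes,
    enumerate_pathways,
    interaction_decomposition,
    mutation_effect,
    pathway_trajectory,
    rank_largest_effect,
    reversion_symmetry,
    round_half_away,
)

ANC = "GAP"


def additive_table(sites, baseline=0.6, effects=(-0.05, -0.02, 0.03)):
    table = GenotypePhenotypeTable(sites, ["y"])
    for g in enumerate_genotypes(sites):
        log_y = baseline + sum(
            e for s, e in zip(sites, effects) if g.is_derived_at(s.label)
        )
        table.set_value(g.code, "y", 10**log_y, 0.01, 3)
    return table


# ---------------------------------------------------------------------------
# oracle: brute-force interaction solve (independent of the package path)
# ---------------------------------------------------------------------------

def brute_force_terms(table, trait):
    """Fit all 2^k interaction coefficients by exhaustive linear solve."""
    sites = table.sites
    k = len(sites)
    subsets = [
        tuple(c) for r in range(k + 1) for c in itertools.combinations(range(k), r)
    ]
    genotypes = list(itertools.product([0, 1], repeat=k))
    X = np.array(
        [
            [int(all(g[i] for i in sub)) for sub in subsets]
            for g in genotypes
        ],
        float,
    )
    y = []
    for g in genotypes:
        code = "".join(
            s.derived if b else s.ancestral for s, b in zip(sites, g)
        )
        y.append(math.log10(table.mean(code, trait)))
    beta = np.linalg.solve(X, np.array(y))
    return {
        tuple(sites[i].label for i in sub): b for sub, b in zip(subsets, beta)
    }


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

class TestEnumeration:
    def test_three_sites(self, alpha_sites):
        gts = enumerate_genotypes(alpha_sites)
        assert len(gts) == 8
        codes = [g.code for g in gts]
        assert codes[0] == "GAP" and codes[-1] == "SVA"
        assert len(codes) - 2 == 6  # six mutational intermediates

    def test_two_sites(self, beta_sites):
        gts = enumerate_genotypes(beta_sites)
        assert len(gts) - 2 == 2
        assert gts[0].code == "TD" and gts[-1].code == "SE"

    def test_one_site(self):
        gts = enumerate_genotypes([SiteDef("s", "A", "V")])
        assert len(gts) - 2 == 0

    def test_duplicate_labels_rejected(self):
        with pytest.raises(InvalidSitesError):
            enumerate_genotypes(
                [SiteDef("s", "A", "V"), SiteDef("s", "G", "S")]
            )

    def test_deterministic_order(self, alpha_sites):
        assert [g.code for g in enumerate_genotypes(alpha_sites)] == [
            g.code for g in enumerate_genotypes(alpha_sites)
        ]

    @pytest.mark.parametrize("k,expected", [(2, 2), (3, 6), (4, 24)])
    def test_pathway_counts(self, k, expected):
        sites = [SiteDef(f"s{i}", "A", "V") for i in range(k)]
        assert len(enumerate_pathways(sites)) == expected

    def test_pathway_size_limit(self):
        sites = [SiteDef(f"s{i}", "A", "V") for i in range(9)]
        with pytest.raises(SizeLimitError):
            enumerate_pathways(sites)


# ---------------------------------------------------------------------------
# mutation effects
# ---------------------------------------------------------------------------

class TestMutationEffect:
    def test_alpha119_on_ancestor(self, alpha_table):
        anc = Genotype.from_code(alpha_table.sites, ANC)
        eff = mutation_effect(alpha_table, "alpha119", anc, "p50_stripped")
        assert eff.to_code == "GAA"
        assert eff.delta_log10 == pytest.approx(math.log10(3.53 / 4.30), abs=1e-12)
        assert eff.delta_log10 == pytest.approx(-0.0857, abs=5e-5)
        assert round_half_away(eff.percent_reduction) == 18
        assert eff.significant

    def test_first_step_percent_reductions(self, alpha_table):
        anc = Genotype.from_code(alpha_table.sites, ANC)
        expected = {"alpha18": 7, "alpha63": 14, "alpha119": 18}
        for site, pct in expected.items():
            eff = mutation_effect(alpha_table, site, anc, "p50_stripped")
            assert round_half_away(eff.percent_reduction) == pct

    def test_derived_background_rejected(self, alpha_table):
        derived = Genotype.from_code(alpha_table.sites, "GAA")
        with pytest.raises(InvalidSiteStateError):
            mutation_effect(alpha_table, "alpha119", derived, "p50_stripped")

    def test_missing_row_names_genotype(self, alpha_sites):
        table = GenotypePhenotypeTable(alpha_sites, ["y"])
        table.set_value("GAP", "y", 4.3, 0.1, 3)
        anc = Genotype.from_code(alpha_sites, "GAP")
        with pytest.raises(MissingDataError, match="GAA"):
            mutation_effect(table, "alpha119", anc, "y")

    def test_sign_consistency(self, alpha_table):
        anc = Genotype.from_code(alpha_table.sites, ANC)
        for site in ("alpha18", "alpha63", "alpha119"):
            eff = mutation_effect(alpha_table, site, anc, "p50_stripped")
            raw = alpha_table.mean(eff.to_code, "p50_stripped") - alpha_table.mean(
                eff.from_code, "p50_stripped"
            )
            assert math.copysign(1, eff.delta_log10) == math.copysign(1, raw)


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

class TestPathways:
    def test_reference_trajectory(self, alpha_table):
        from hbcube.landscape import Pathway

        pw = pathway_trajectory(
            alpha_table, Pathway(order=("alpha119", "alpha63", "alpha18")),
            "p50_stripped",
        )
        p50s = [alpha_table.mean(c, "p50_stripped") for c in pw.genotype_codes]
        assert p50s == [4.30, 3.53, 3.52, 3.42]

    def test_telescoping_exact(self, alpha_table):
        endpoint = math.log10(3.42 / 4.30)
        assert endpoint == pytest.approx(-0.0994, abs=5e-5)
        for skeleton in enumerate_pathways(alpha_table.sites):
            pw = pathway_trajectory(alpha_table, skeleton, "p50_stripped")
            assert pw.total_delta_log10 == pytest.approx(endpoint, abs=1e-12)

    def test_telescoping_k_auto(self, alpha_table):
        endpoint = math.log10(0.109 / 0.170)
        for skeleton in enumerate_pathways(alpha_table.sites):
            pw = pathway_trajectory(alpha_table, skeleton, "k_auto")
            assert pw.total_delta_log10 == pytest.approx(endpoint, abs=1e-12)

    def test_additive_landscape_identical_step_multisets(self, alpha_sites):
        table = additive_table(alpha_sites)
        multisets = []
        for skeleton in enumerate_pathways(alpha_sites):
            pw = pathway_trajectory(table, skeleton, "y")
            multisets.append(
                sorted(round(s.effect.delta_log10, 9) for s in pw.steps)
            )
        assert all(m == multisets[0] for m in multisets)

    def test_missing_corner_fails(self, alpha_sites):
        from hbcube.landscape import Pathway

        table = GenotypePhenotypeTable(alpha_sites, ["y"])
        table.set_value("GAP", "y", 4.3, 0.1, 3)
        with pytest.raises(MissingDataError):
            pathway_trajectory(
                table, Pathway(order=("alpha18", "alpha63", "alpha119")), "y"
            )


class TestRankLargestEffect:
    def test_reference_split(self, alpha_table):
        summary = rank_largest_effect(alpha_table, "p50_stripped", "decrease")
        assert summary.counts == {"alpha18": 0, "alpha63": 2, "alpha119": 4}
        assert summary.tied_pathways == 0

    def test_alpha63_wins_exactly_when_first(self, alpha_table):
        summary = rank_largest_effect(alpha_table, "p50_stripped", "decrease")
        for pw, winners in summary.winners:
            if winners == ("alpha63",):
                assert pw.order[0] == "alpha63"
            if pw.order[0] == "alpha63":
                assert winners == ("alpha63",)

    def test_flat_landscape_all_tied(self, alpha_sites):
        table = GenotypePhenotypeTable(alpha_sites, ["y"])
        for g in enumerate_genotypes(alpha_sites):
            table.set_value(g.code, "y", 1.0, 0.01, 3)
        summary = rank_largest_effect(table, "y", "decrease")
        assert summary.tied_pathways == 6
        assert all(c == 0 for c in summary.counts.values())

    def test_log_and_percent_framings_agree(self, alpha_table):
        # per pathway, the winner under |delta_log10| equals the winner
        # under raw-scale percent reduction
        summary = rank_largest_effect(alpha_table, "p50_stripped", "decrease")
        for pw, winners in summary.winners:
            pct_winner = max(
                pw.steps, key=lambda s: s.effect.percent_reduction
            ).effect.site
            assert winners == (pct_winner,)

    def test_permutation_invariance(self, alpha_table):
        reordered = GenotypePhenotypeTable(
            alpha_table.sites[::-1], alpha_table.traits
        )
        for code in alpha_table.genotypes:
            tv = alpha_table.value(code, "p50_stripped")
            reordered.set_value(code[::-1], "p50_stripped", tv.mean, tv.sem, tv.n)
        assert rank_largest_effect(
            reordered, "p50_stripped", "decrease"
        ).counts == rank_largest_effect(
            alpha_table, "p50_stripped", "decrease"
        ).counts


# ---------------------------------------------------------------------------
# backgrounds, reversion, cycles
# ---------------------------------------------------------------------------

class TestBackgrounds:
    def test_alpha119_reduces_p50_on_all_four_backgrounds(self, alpha_table):
        effects = effects_on_all_backgrounds(alpha_table, "alpha119", "p50_stripped")
        assert len(effects) == 4
        assert all(e.delta_log10 < 0 for e in effects)
        transitions = {(e.from_code, e.to_code) for e in effects}
        assert transitions == {
            ("GAP", "GAA"), ("GVP", "GVA"), ("SAP", "SAA"), ("SVP", "SVA"),
        }

    def test_alpha63_k_auto_compensated_by_alpha18(self, alpha_table):
        effects = {
            e.from_code: e
            for e in effects_on_all_backgrounds(alpha_table, "alpha63", "k_auto")
        }
        # >2-fold increases on Gly-alpha18 backgrounds
        for code in ("GAP", "GAA"):
            assert 10 ** effects[code].delta_log10 > 2.0
        # ~no increase on Ser-alpha18 backgrounds
        for code in ("SAP", "SAA"):
            assert 10 ** effects[code].delta_log10 < 1.1

    def test_single_site_landscape(self):
        sites = [SiteDef("s", "A", "V")]
        table = GenotypePhenotypeTable(sites, ["y"])
        table.set_value("A", "y", 2.0, 0.1, 3)
        table.set_value("V", "y", 1.0, 0.1, 3)
        assert len(effects_on_all_backgrounds(table, "s", "y")) == 1


class TestReversionSymmetry:
    def test_alpha119_forward_and_reverted(self, alpha_table):
        pairs = reversion_symmetry(alpha_table, "alpha119", "p50_stripped")
        assert len(pairs) == 6  # C(4, 2) background pairs
        match = [
            p for p in pairs
            if p.background_fwd.code == "GAP" and p.background_rev.code == "SVA"
        ]
        assert len(match) == 1
        pair = match[0]
        assert pair.forward_delta_log10 == pytest.approx(-0.0857, abs=5e-5)
        # reversion on the fully derived background: log10(3.88/3.42)
        assert pair.reverse_delta_log10 == pytest.approx(
            math.log10(3.88 / 3.42), abs=1e-12
        )
        assert pair.reverse_delta_log10 == pytest.approx(0.0548, abs=5e-5)

    def test_additive_landscape_zero_asymmetry(self, alpha_sites):
        table = additive_table(alpha_sites)
        for site in ("alpha18", "alpha63", "alpha119"):
            for pair in reversion_symmetry(table, site, "y"):
                assert pair.asymmetry_index == pytest.approx(0.0, abs=1e-9)

    def test_missing_corner(self, alpha_sites):
        table = GenotypePhenotypeTable(alpha_sites, ["y"])
        table.set_value("GAP", "y", 4.3, 0.1, 3)
        with pytest.raises(MissingDataError):
            reversion_symmetry(table, "alpha119", "y")


class TestDoubleMutantCycle:
    def test_cycle_a_epistasis(self, alpha_table):
        cyc = double_mutant_cycle(
            alpha_table, "alpha18", "alpha63", {"alpha119": "P"}, "k_auto"
        )
        expected = math.log10(0.159 / 0.149) - math.log10(0.399 / 0.170)
        assert cyc.epistasis_log10 == pytest.approx(expected, abs=1e-12)
        assert cyc.epistasis_log10 == pytest.approx(-0.342, abs=5e-4)

    def test_cycle_a_full_compensation(self, alpha_table):
        cyc = double_mutant_cycle(
            alpha_table, "alpha18", "alpha63", {"alpha119": "P"}, "k_auto"
        )
        assert cyc.compensation_ratio == pytest.approx(0.159 / 0.170, abs=1e-12)
        assert cyc.compensation_ratio == pytest.approx(0.94, abs=0.005)

    def test_symmetric_in_sites(self, alpha_table):
        a = double_mutant_cycle(
            alpha_table, "alpha18", "alpha63", {"alpha119": "P"}, "k_auto"
        )
        b = double_mutant_cycle(
            alpha_table, "alpha63", "alpha18", {"alpha119": "P"}, "k_auto"
        )
        assert a.epistasis_log10 == pytest.approx(b.epistasis_log10, abs=1e-12)

    def test_additive_table_zero_epistasis(self, alpha_sites):
        table = additive_table(alpha_sites)
        cyc = double_mutant_cycle(
            table, "alpha18", "alpha63", {"alpha119": "P"}, "y"
        )
        assert cyc.epistasis_log10 == pytest.approx(0.0, abs=1e-9)

    def test_missing_corner(self, alpha_sites):
        table = GenotypePhenotypeTable(alpha_sites, ["y"])
        for code in ("GAP", "SAP", "GVP"):
            table.set_value(code, "y", 1.0, 0.1, 3)
        with pytest.raises(MissingDataError):
            double_mutant_cycle(
                table, "alpha18", "alpha63", {"alpha119": "P"}, "y"
            )


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_cycle_epistasis_matches_brute_force_solve(self, k):
        rng = np.random.default_rng(k)
        sites = tuple(SiteDef(f"s{i}", "A", "V") for i in range(k))
        # random landscape with main effects and pairwise terms only
        mains = {s.label: rng.normal(0, 0.1) for s in sites}
        pairs = {
            (sites[i].label, sites[j].label): rng.normal(0, 0.05)
            for i in range(k) for j in range(i + 1, k)
        }
        table = GenotypePhenotypeTable(sites, ["y"])
        for g in enumerate_genotypes(sites):
            on = {s.label for s in sites if g.is_derived_at(s.label)}
            log_y = 0.5 + sum(mains[l] for l in on) + sum(
                c for (a, b), c in pairs.items() if a in on and b in on
            )
            table.set_value(g.code, "y", 10**log_y, 0.01, 3)

        oracle = brute_force_terms(table, "y")
        pkg = interaction_decomposition(table, "y")
        for key, val in oracle.items():
            assert pkg[key] == pytest.approx(val, abs=1e-10)
        # with pairwise-only truth, every cycle recovers its planted term
        # on every background
        import itertools as it

        for (a, b), coef in pairs.items():
            others = [s for s in sites if s.label not in (a, b)]
            for states in it.product(*[(s.ancestral, s.derived) for s in others]):
                bg = dict(zip([s.label for s in others], states))
                cyc = double_mutant_cycle(table, a, b, bg, "y")
                assert cyc.epistasis_log10 == pytest.approx(coef, abs=1e-10)

    def test_reference_table_decomposition_reproduces_means(self, alpha_table):
        terms = interaction_decomposition(alpha_table, "p50_stripped")
        oracle = brute_force_terms(alpha_table, "p50_stripped")
        for key, val in oracle.items():
            assert terms[key] == pytest.approx(val, abs=1e-10)
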