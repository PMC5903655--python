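"""Bundled reference fixtures.

Transcribed published genotype-phenotype summaries for the bar-headed
goose / greylag goose hemoglobin system: stripped P50 (torr, mean +/- SEM
over triplicates), anion-sensitivity indices (delta log10 P50 under KCl,
IHP and KCl+IHP) and autoxidation rates (h^-1, mean +/- SEM), for the
two wildtype species, their reconstructed ancestor and every mutational
intermediate.  Also ships an *emulated* Anserinae tree + site-state
matrix: the published per-species matrix is not machine-readable, so the
fixture is constructed to make the documented ancestral states (GAP/TD)
and branch substitution counts (3 on the bar-headed goose terminal
branch, 2 on the stem of the other Anser species) the unique
parsimonious solution.  It is an emulation, not a transcription.
"""

from __future__ import annotations

from .ancestry import PhyloTree, SiteStateMatrix
from .landscape import GenotypePhenotypeTable, SiteDef

__all__ = [
    "alpha_sites",
    "beta_sites",
    "combined_sites",
    "goose_alpha_table",
    "goose_beta_table",
    "goose_combined_table",
    "anserinae_tree",
    "anserinae_states",
    "ALPHA_ROWS",
    "BETA_ROWS",
    "ANCESTOR_NODE",
]

# α-chain sites, ancestral -> derived in the bar-headed goose lineage
ALPHA_SITES = (
    ("alpha18", "G", "S"),
    ("alpha63", "A", "V"),
    ("alpha119", "P", "A"),
)
# β-chain sites, ancestral -> derived in the greylag goose lineage
BETA_SITES = (
    ("beta4", "T", "S"),
    ("beta125", "D", "E"),
)

# code -> (p50_stripped mean, sem, dlog_kcl, dlog_ihp, dlog_kcl_ihp,
#          k_auto mean, k_auto sem); triplicate measurements throughout
ALPHA_ROWS: dict[str, tuple[float, float, float, float, float, float, float]] = {
    "GAP": (4.30, 0.06, 0.092, 0.815, 0.630, 0.170, 0.014),  # ancestor
    "SAP": (3.98, 0.03, 0.098, 0.653, 0.523, 0.149, 0.011),
    "GVP": (3.68, 0.01, 0.072, 0.742, 0.584, 0.399, 0.067),
    "GAA": (3.53, 0.08, 0.111, 0.745, 0.693, 0.164, 0.026),
    "SVP": (3.88, 0.04, 0.027, 0.691, 0.573, 0.159, 0.009),
    "SAA": (3.32, 0.05, 0.156, 0.870, 0.742, 0.154, 0.013),
    "GVA": (3.52, 0.04, 0.079, 0.708, 0.589, 0.424, 0.036),
    "SVA": (3.42, 0.06, 0.115, 0.749, 0.643, 0.109, 0.017),  # bar-headed goose
}

BETA_ROWS: dict[str, tuple[float, float, float, float, float, float, float]] = {
    "TD": (4.30, 0.06, 0.092, 0.815, 0.630, 0.170, 0.014),  # ancestor (= GAP)
    "SD": (4.10, 0.05, 0.052, 0.729, 0.601, 0.132, 0.014),
    "TE": (4.01, 0.04, 0.104, 0.774, 0.549, 0.156, 0.019),
    "SE": (4.10, 0.04, 0.082, 0.843, 0.680, 0.112, 0.019),  # greylag goose
}

_TRAITS = (
    "p50_stripped",
    "dlog_kcl",
    "dlog_ihp",
    "dlog_kcl_ihp",
    "k_auto",
)


def alpha_sites() -> tuple[SiteDef, ...]:
    return tuple(SiteDef(*s) for s in ALPHA_SITES)


def beta_sites() -> tuple[SiteDef, ...]:
    return tuple(SiteDef(*s) for s in BETA_SITES)


def combined_sites() -> tuple[SiteDef, ...]:
    return alpha_sites() + beta_sites()


def _fill(table: GenotypePhenotypeTable, code: str, row: tuple) -> None:
    p50, p50_se, dk, di, dki, ka, ka_se = row
    table.set_value(code, "p50_stripped", p50, p50_se, 3)
    table.set_value(code, "dlog_kcl", dk)
    table.set_value(code, "dlog_ihp", di)
    table.set_value(code, "dlog_kcl_ihp", dki)
    table.set_value(code, "k_auto", ka, ka_se, 3)


def goose_alpha_table() -> GenotypePhenotypeTable:
    """Full 2^3 hypercube over the α-chain sites (GAP ... SVA)."""
    table = GenotypePhenotypeTable(alpha_sites(), _TRAITS)
    for code, row in ALPHA_ROWS.items():
        _fill(table, code, row)
    return table


def goose_beta_table() -> GenotypePhenotypeTable:
    """Full 2^2 hypercube over the β-chain sites (TD ... SE)."""
    table = GenotypePhenotypeTable(beta_sites(), _TRAITS)
    for code, row in BETA_ROWS.items():
        _fill(table, code, row)
    return table


def goose_combined_table() -> GenotypePhenotypeTable:
    """All 11 measured rHbs on the joint 5-site lattice (sparse).

    Genotypes are coded over alpha18/alpha63/alpha119/beta4/beta125; the
    shared ancestor is GAPTD.  Only 11 of the 32 corners were measured,
    so hypercube operations fail loudly here; the table serves
    genotype-level pleiotropy pairing.
    """
    table = GenotypePhenotypeTable(combined_sites(), _TRAITS)
    for code, row in ALPHA_ROWS.items():
        _fill(table, code + "TD", row)
    for code, row in BETA_ROWS.items():
        if code == "TD":  # ancestor already present as GAPTD
            continue
        _fill(table, "GAP" + code, row)
    return table


# ---------------------------------------------------------------------------
# emulated Anserinae phylogeny fixture
# ---------------------------------------------------------------------------

ANCESTOR_NODE = "AncAnser"

_NEWICK = (
    "((((bar_headed_goose,(greylag_goose,swan_goose,bean_goose,snow_goose)"
    "AnserRest)AncAnser,(canada_goose,hawaiian_goose)Branta)TrueGeese,"
    "(mute_swan,black_swan,trumpeter_swan)Cygnus)CoreAnserinae,"
    "(coscoroba_swan,cape_barren_goose,magpie_goose,freckled_duck)Outgroup)"
    "Anserinae;"
)

#: tips carrying the derived state at the β sites (non-bar-headed Anser clade)
_BETA_DERIVED_TIPS = ("greylag_goose", "swan_goose", "bean_goose", "snow_goose")


def anserinae_tree() -> PhyloTree:
    """Rooted 14-tip waterfowl tree; 'AncAnser' labels the Anser MRCA."""
    return PhyloTree.from_newick(_NEWICK)


def anserinae_states() -> SiteStateMatrix:
    """Site states for the 14 tips at the five variable sites.

    Bar-headed goose alone carries S/V/A at the α sites; the four other
    Anser species alone carry S/E at the β sites; everything else is
    ancestral (G/A/P and T/D).
    """
    tree = anserinae_tree()
    states: dict[str, dict[str, str]] = {}
    for tip in tree.tip_labels:
        alpha = (
            {"alpha18": "S", "alpha63": "V", "alpha119": "A"}
            if tip == "bar_headed_goose"
            else {"alpha18": "G", "alpha63": "A", "alpha119": "P"}
        )
        beta = (
            {"beta4": "S", "beta125": "E"}
            if tip in _BETA_DERIVED_TIPS
            else {"beta4": "T", "beta125": "D"}
        )
        states[tip] = {**alpha, **beta}
    return SiteStateMatrix(states)
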