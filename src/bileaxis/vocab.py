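"""Controlled vocabularies for the bile-acid (BA) axis analysis.

Bacterial transformation of primary bile acids (cholic acid, CA, and
chenodeoxycholic acid, CDCA) into secondary bile acids proceeds through a
small set of well-characterised enzymes: bile-salt hydrolase (BSH)
deconjugates glycine/taurine conjugates, the 7alpha-/7beta-hydroxysteroid
dehydrogenases (HSDH) epimerise CDCA to ursodeoxycholic acid (UDCA), and
the ten-gene *bai* operon carries out 7-dehydroxylation of CA/CDCA/UDCA to
deoxycholic acid (DCA) and lithocholic acid (LCA).

This module fixes the enzyme vocabulary, the default enzyme-to-pathway map,
the 24-analyte faecal BA panel with its primary/secondary classification,
and the taxonomic rank ladder used by the lowest-common-ancestor assignment.
All of these are defaults; the analysis functions accept custom maps.
"""

from __future__ import annotations

from types import MappingProxyType

# --- enzymes -----------------------------------------------------------------

HSDH_ALPHA = "7alpha-HSDH"
HSDH_BETA = "7beta-HSDH"

BAI_GENES: tuple[str, ...] = (
    "BaiB", "BaiF", "BaiA", "BaiH", "BaiI",
    "BaiN", "BaiCD", "BaiE", "BaiA2", "BaiG",
)

#: The 13 BA-metabolism enzymes profiled from the gene catalogue.
ENZYMES: tuple[str, ...] = ("BSH", HSDH_ALPHA, HSDH_BETA) + BAI_GENES

#: Enzyme -> pathway map used to call potential producer genera.
#: UDCA synthesis needs an HSDH; LCA and DCA synthesis both run through the
#: bai operon (7-dehydroxylation of CDCA/UDCA and of CA respectively), so
#: they share the same gene set by default.  BSH deconjugates but feeds no
#: single synthesis pathway and is deliberately absent.
DEFAULT_PATHWAYS: MappingProxyType = MappingProxyType({
    "UDCA-synthesis": frozenset({HSDH_ALPHA, HSDH_BETA}),
    "LCA-synthesis": frozenset(BAI_GENES),
    "DCA-synthesis": frozenset(BAI_GENES),
})

#: Minimum number of distinct bai genes for a genus to count as carrying a
#: (near-)complete operon.
DEFAULT_BAI_MIN_COUNT = 5

# --- taxonomy ----------------------------------------------------------------

RANKS: tuple[str, ...] = (
    "superkingdom", "phylum", "class", "order", "family", "genus", "species",
)
GENUS_RANK_INDEX = RANKS.index("genus")

# --- bile-acid panel ---------------------------------------------------------

#: The 24-analyte targeted faecal panel (nmol/g).  The first 17 are the
#: named analytes; the remainder are common conjugates completing the panel.
BA_PANEL: tuple[str, ...] = (
    "UDCA", "bUDCA", "HCA", "7-KetoLCA", "3-DHCA", "6-KetoLCA", "CDCA",
    "TCA", "CA", "GUDCA", "TCDCA", "TUDCA", "dehydroLCA", "12-KetoLCA",
    "LCA", "GDCA", "DCA",
    "GCA", "GCDCA", "TDCA", "GLCA", "TLCA", "HDCA", "7-KetoDCA",
)

#: name -> {"class": primary|secondary, "conjugation": free|glycine|taurine,
#: "parent": core BA}.  Primary = host-synthesised CA/CDCA and their amino
#: acid conjugates; everything microbially derived is secondary.
BA_CLASS_MAP: MappingProxyType = MappingProxyType({
    "CA":          {"class": "primary",   "conjugation": "free",    "parent": "CA"},
    "CDCA":        {"class": "primary",   "conjugation": "free",    "parent": "CDCA"},
    "TCA":         {"class": "primary",   "conjugation": "taurine", "parent": "CA"},
    "GCA":         {"class": "primary",   "conjugation": "glycine", "parent": "CA"},
    "TCDCA":       {"class": "primary",   "conjugation": "taurine", "parent": "CDCA"},
    "GCDCA":       {"class": "primary",   "conjugation": "glycine", "parent": "CDCA"},
    "UDCA":        {"class": "secondary", "conjugation": "free",    "parent": "UDCA"},
    "bUDCA":       {"class": "secondary", "conjugation": "free",    "parent": "UDCA"},
    "GUDCA":       {"class": "secondary", "conjugation": "glycine", "parent": "UDCA"},
    "TUDCA":       {"class": "secondary", "conjugation": "taurine", "parent": "UDCA"},
    "DCA":         {"class": "secondary", "conjugation": "free",    "parent": "DCA"},
    "GDCA":        {"class": "secondary", "conjugation": "glycine", "parent": "DCA"},
    "TDCA":        {"class": "secondary", "conjugation": "taurine", "parent": "DCA"},
    "LCA":         {"class": "secondary", "conjugation": "free",    "parent": "LCA"},
    "GLCA":        {"class": "secondary", "conjugation": "glycine", "parent": "LCA"},
    "TLCA":        {"class": "secondary", "conjugation": "taurine", "parent": "LCA"},
    "HCA":         {"class": "secondary", "conjugation": "free",    "parent": "HCA"},
    "HDCA":        {"class": "secondary", "conjugation": "free",    "parent": "HDCA"},
    "7-KetoLCA":   {"class": "secondary", "conjugation": "free",    "parent": "LCA"},
    "6-KetoLCA":   {"class": "secondary", "conjugation": "free",    "parent": "LCA"},
    "12-KetoLCA":  {"class": "secondary", "conjugation": "free",    "parent": "LCA"},
    "dehydroLCA":  {"class": "secondary", "conjugation": "free",    "parent": "LCA"},
    "3-DHCA":      {"class": "secondary", "conjugation": "free",    "parent": "CA"},
    "7-KetoDCA":   {"class": "secondary", "conjugation": "free",    "parent": "DCA"},
})

SECONDARY_BAS: frozenset[str] = frozenset(
    name for name, info in BA_CLASS_MAP.items() if info["class"] == "secondary"
)
PRIMARY_BAS: frozenset[str] = frozenset(BA_PANEL) - SECONDARY_BAS

# --- genus pool with consistent lineages ------------------------------------

_KNOWN_GENERA: dict[str, tuple[str, str, str, str]] = {
    # genus -> (phylum, class, order, family)
    "Blautia":          ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Roseburia":        ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Eubacterium":      ("Firmicutes", "Clostridia", "Clostridiales", "Eubacteriaceae"),
    "Faecalibacterium": ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    "Ruminococcus":     ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    "Butyricicoccus":   ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae"),
    "Clostridium":      ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae"),
    "Dialister":        ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae"),
    "Lactobacillus":    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    "Bacteroides":      ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
    "Prevotella":       ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    "Bifidobacterium":  ("Actinobacteria", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae"),
    "Escherichia":      ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae"),
    "Akkermansia":      ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Akkermansiaceae"),
}

_SYNTH_PHYLA = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria")


def genus_lineage(genus: str) -> tuple[str, ...]:
    """Full 7-rank lineage for a genus in the simulation's taxonomy.

    Known gut genera get their real lineages; synthetic fill-in genera
    (``Genus_NNN``) get deterministic lineages spread over four phyla so
    that decoy hits can disagree at any rank.
    """
    if genus in _KNOWN_GENERA:
        phylum, clazz, order, family = _KNOWN_GENERA[genus]
    else:
        idx = abs(hash_name(genus))
        phylum = _SYNTH_PHYLA[idx % len(_SYNTH_PHYLA)]
        clazz = f"Class_{idx % 7:02d}"
        order = f"Order_{idx % 11:02d}"
        family = f"Family_{idx % 17:02d}"
    return ("Bacteria", phylum, clazz, order, family, genus, f"{genus} sp.")


def hash_name(name: str) -> int:
    """Stable (non-salted) string hash; Python's ``hash`` is salted per run."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31)
    return h


def genus_pool(n: int) -> list[str]:
    """First *n* genus names: the curated gut genera, then synthetic fill."""
    pool = list(_KNOWN_GENERA)
    pool += [f"Genus_{i:03d}" for i in range(len(pool), max(n, len(pool)))]
    return pool[:n]
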