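"""Small bundled example data for demos and regression checks.

The hub sets below come from four independent curations of the actin-dynamics
signalling network around sperm capacitation — a manually compiled database,
two text-mining tools, and a pathway-database reference.  The four curations
disagree widely on which molecules are hubs; the actin label itself (written
with different casings by the different curations) is the only hub all four
share, which makes the collection a good exercise for case-insensitive
overlap analysis.
"""

from __future__ import annotations

__all__ = ["actin_hub_sets"]


def actin_hub_sets() -> dict[str, list[str]]:
    """Hub label sets of four actin-signalling network curations."""
    return {
        "manual": [
            "PKA", "Actin polymerization", "Tyrosine phosphorylation",
            "[Ca2+]i", "cAMP", "ROS", "Actin depolymerisation", "F-actin",
            "PLD", "Rho GTPase", "H2O2", "PIP2 cleavage", "Arp2/3 complex",
            "ADF/cofilin", "EGFR", "HCO3-", "PKC", "Actin",
        ],
        "cooccurrence_mining": [
            "RHOA", "MSP", "EGFR", "LIMK", "CDC42", "GNA13", "ROCK2",
            "LIMK2", "ACE", "AKAP4", "AKAP3", "PRKAR2", "ROPN1", "actin",
        ],
        "literature_search": ["ACTIN"],
        "pathway_db": [
            "RAC1", "ROCK1", "PAK4", "RHOA", "CDC42", "ACTIN", "ARHGEF7",
            "MYL12B", "RRAS2",
        ],
    }
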