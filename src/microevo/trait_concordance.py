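"""Phenotype tables, genotype-derived trait predictions, and concordance.

Observed phenotypes (growth assays) and predicted capabilities (pathway
gene-set completeness) are both strain x trait tables over {+, -, NA};
concordance compares them cell by cell and lists every inconsistency -
the cells where the genome predicts a capability the strain does not show,
or vice versa, which is the signature of regulatory rather than gene-content
divergence.

Transcriptions of the published auxotrophy, phosphorus-source, and
phosphorus-strategy tables ship as packaged TSV fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

SYMBOLS = ("+", "-", "NA")


@dataclass
class TraitTable:
    """Traits as rows, strains as columns; values mostly in {+, -, NA}.

    Rows whose values fall outside the binary symbols (e.g. 3-level
    regulation states) are carried but excluded from binary analyses.
    Comment metadata from the TSV header (e.g. printed column totals) is
    kept in `meta`.
    """

    data: pd.DataFrame
    groups: pd.Series
    notes: pd.Series
    meta: dict = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        return list(self.data.columns)

    @property
    def traits(self) -> list[str]:
        return list(self.data.index)

    def binary(self) -> pd.DataFrame:
        """Rows restricted to those whose entries are all in {+, -, NA}."""
        ok = self.data.isin(SYMBOLS).all(axis=1)
        return self.data[ok]

    def restrict_groups(self, groups) -> "TraitTable":
        keep = self.groups.isin(set(groups))
        return TraitTable(
            self.data[keep.values], self.groups[keep.values], self.notes[keep.values], self.meta
        )


def read_trait_table(path_or_buffer) -> TraitTable:
    meta: dict = {}
    rows = []
    header = None
    with open(path_or_buffer) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if len(parts) > 1 and "=" in parts[1]:
                    meta[parts[0]] = {
                        k: v for k, v in (p.split("=", 1) for p in parts[1:])
                    }
                continue
            if header is None:
                header = line.split("\t")
                continue
            cols = line.split("\t")
            cols += [""] * (len(header) - len(cols))
            rows.append(cols)
    df = pd.DataFrame(rows, columns=header)
    strain_cols = [c for c in header if c not in ("group", "trait", "note")]
    data = df.set_index("trait")[strain_cols]
    groups = df.set_index("trait")["group"]
    notes = df.set_index("trait")["note"] if "note" in df else pd.Series("", index=data.index)
    return TraitTable(data, groups, notes, meta)


def load_packaged_table(name: str) -> TraitTable:
    """Load one of the shipped fixtures: table2_observed, table2_predicted,
    table3_observed, table4_observed."""
    ref = resources.files("microevo.data") / f"{name}.tsv"
    with resources.as_file(ref) as path:
        return read_trait_table(path)


# ---------------------------------------------------------------------------
# genotype-derived predictions


@dataclass
class PathwayDef:
    """A trait is predicted "+" when any one alternative requirement set of
    gene families is fully present."""

    trait: str
    alternatives: list[set[str]]

    def __post_init__(self):
        if not self.alternatives or any(not alt for alt in self.alternatives):
            raise ValueError(f"{self.trait}: alternatives must be non-empty sets")


def predict_trait(present_families: set[str], definition: PathwayDef) -> str:
    return "+" if any(alt <= present_families for alt in definition.alternatives) else "-"


def predict_table(
    families_per_strain: dict[str, set[str]], definitions: list[PathwayDef]
) -> TraitTable:
    strains = sorted(families_per_strain)
    data = pd.DataFrame(
        {
            s: [predict_trait(families_per_strain[s], d) for d in definitions]
            for s in strains
        },
        index=[d.trait for d in definitions],
    )
    groups = pd.Series("prediction", index=data.index)
    notes = pd.Series("", index=data.index)
    return TraitTable(data, groups, notes)


# ---------------------------------------------------------------------------
# concordance


@dataclass
class Inconsistency:
    strain: str
    trait: str
    observed: str
    predicted: str


@dataclass
class ConcordanceReport:
    agreement: pd.DataFrame  # True/False/NA per cell
    inconsistencies: list[Inconsistency]
    concordant_per_strain: pd.Series
    discordant_per_strain: pd.Series


def concordance(observed: TraitTable, predicted: TraitTable) -> ConcordanceReport:
    """Cell-wise agreement over the traits and strains shared by name.

    NA cells and non-binary rows are excluded.  Trait names present in one
    table but not the other raise, listing the mismatch."""
    obs = observed.binary()
    pred = predicted.binary()
    missing = set(obs.index) ^ set(pred.index)
    if missing:
        raise ValueError(f"unmatched trait names: {sorted(missing)}")
    strains = [s for s in obs.columns if s in set(pred.columns)]
    obs = obs[strains]
    pred = pred.loc[obs.index, strains]
    valid = (obs != "NA") & (pred != "NA")
    agree = (obs == pred).where(valid)
    inconsistencies = [
        Inconsistency(s, t, obs.loc[t, s], pred.loc[t, s])
        for t in obs.index
        for s in strains
        if valid.loc[t, s] and obs.loc[t, s] != pred.loc[t, s]
    ]
    concordant = (agree == True).sum(axis=0)  # noqa: E712 - NA-aware mask
    discordant = (agree == False).sum(axis=0)  # noqa: E712
    return ConcordanceReport(agree, inconsistencies, concordant, discordant)


def summarize_auxotrophies(observed: TraitTable) -> pd.Series:
    """Per-strain count of "-" cells (auxotrophies) in the observation table."""
    return (observed.binary() == "-").sum(axis=0)
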