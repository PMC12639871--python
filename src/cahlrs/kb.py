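"""Curated pathogenic-variant knowledge base for 21-hydroxylase deficiency.

ACMG-style classification is carried as a curated lookup (P / LP / VUS) with
the clinically annotated phenotype subtype per variant: SW (salt-wasting),
SV (simple virilising), NC (non-classic), or unknown.  Structural classes
(30-kb-deletion chimeras, named by junction bin) are entries like any other.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

CLASSIFICATIONS = {"P", "LP", "VUS"}
PHENOTYPES = {"SW", "SV", "NC"}


@dataclass(frozen=True)
class KBEntry:
    name: str
    classification: str  # P | LP | VUS
    phenotype: str       # SW | SV | NC | unknown
    allele_tally: int = 0


class VariantKB:
    def __init__(self, entries: dict[str, KBEntry]):
        self.entries = entries

    def __len__(self):
        return len(self.entries)

    def get(self, name: str) -> KBEntry | None:
        return self.entries.get(name)

    def classification(self, name: str) -> str:
        e = self.entries.get(name)
        return e.classification if e else "unknown"

    def phenotype(self, name: str) -> str:
        e = self.entries.get(name)
        return e.phenotype if e else "unknown"

    def is_pathogenic(self, name: str) -> bool:
        """P and LP count toward pathogenic alleles; VUS never does."""
        return self.classification(name) in ("P", "LP")

    @property
    def pathogenic_names(self):
        return [n for n, e in self.entries.items()
                if e.classification in ("P", "LP")]

    def structural_names(self):
        return [n for n in self.entries if not n.startswith("c.")]


def load_variant_kb(path_or_handle) -> VariantKB:
    """Read a TSV/CSV table with columns name, classification, phenotype
    (optional allele_tally).  Duplicate names and missing classifications
    are errors; unrecognized phenotype strings map to "unknown".
    """
    if hasattr(path_or_handle, "read"):
        text = path_or_handle.read()
    else:
        with open(path_or_handle) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return VariantKB({})
    dialect = "excel-tab" if "\t" in lines[0] else "excel"
    reader = csv.DictReader(lines, dialect=dialect)
    entries: dict[str, KBEntry] = {}
    for row in reader:
        name = (row.get("name") or "").strip()
        if not name:
            raise ValueError("row with empty variant name")
        if name in entries:
            raise ValueError(f"duplicate knowledge-base entry: {name}")
        cls = (row.get("classification") or "").strip()
        if cls not in CLASSIFICATIONS:
            raise ValueError(f"{name}: missing or invalid classification {cls!r}")
        pheno = (row.get("phenotype") or "").strip()
        if pheno not in PHENOTYPES:
            pheno = "unknown"
        tally = int(row.get("allele_tally") or 0)
        entries[name] = KBEntry(name, cls, pheno, tally)
    return VariantKB(entries)


def default_kb() -> VariantKB:
    """The packaged knowledge base: 11 pathogenic entries (8 SNV/indel + 3
    structural chimera classes) plus the cohort's VUS/LP annotations."""
    with resources.files("cahlrs.data").joinpath("variant_kb.tsv").open() as fh:
        return load_variant_kb(fh)
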