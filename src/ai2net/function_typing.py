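"""Functional typing of AI-2 receptors from output-domain architecture.

A dCache_1-type receptor transduces its periplasmic ligand signal through a
cytoplasmic output domain; the output-domain architecture therefore decides
the functional module: MCP (chemotaxis), CSP (c-di-GMP turnover, GGDEF/EAL),
HK (histidine kinase, DHp + ATPase), STK (Ser/Thr kinase), SP (PP2C-family
serine phosphatase) or AC/GC (nucleotide cyclase); anything else is
``uncharacterized``.  LuxP, LsrB and GAPES1 receptors have canonical
modules (LuxPQ two-component signalling, Lsr import, c-di-GMP synthesis).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .genomes import SpeciesGenome
from .receptors import DomainHit, ReceptorCall

UNCHARACTERIZED = "uncharacterized"

CANONICAL_MODULES = {
    "LuxP": "LuxPQ",
    "LsrB": "Lsr-import",
    "GAPES1": "CSP",
}


@dataclass(frozen=True)
class ModuleDefinition:
    """One functional module and the domain accessions that define it."""

    name: str
    any_of: frozenset[str] = frozenset()
    all_of: frozenset[str] = frozenset()

    def matches(self, accessions: frozenset[str]) -> bool:
        if self.all_of and not self.all_of <= accessions:
            return False
        if self.any_of and not self.any_of & accessions:
            return False
        return bool(self.any_of or self.all_of)


@dataclass(frozen=True)
class ModuleRegistry:
    """Ordered module definitions; first match in precedence order wins."""

    definitions: tuple[ModuleDefinition, ...]

    def classify(self, accessions: Iterable[str]) -> tuple[str, tuple[str, ...]]:
        """Return (assigned module, all co-matching modules)."""
        accs = frozenset(accessions)
        matching = tuple(d.name for d in self.definitions if d.matches(accs))
        return (matching[0] if matching else UNCHARACTERIZED), matching


def load_module_registry(path: str | Path | None = None) -> ModuleRegistry:
    """Load the module-definition manifest (default: packaged manifest)."""
    if path is None:
        raw = yaml.safe_load(
            resources.files("ai2net.data").joinpath("modules.yaml").read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    definitions = []
    for name in raw["precedence"]:
        entry = raw["modules"][name]
        definitions.append(ModuleDefinition(
            name=name,
            any_of=frozenset(entry.get("any_of", [])),
            all_of=frozenset(entry.get("all_of", [])),
        ))
    return ModuleRegistry(definitions=tuple(definitions))


def classify_architecture(
    locus_tag: str,
    domain_hits: Iterable[DomainHit],
    registry: ModuleRegistry | None = None,
) -> tuple[str, tuple[str, ...]]:
    """Assign a functional module from a protein's full domain scan.

    Order- and duplicate-invariant: only the set of hit accessions on the
    protein matters.  Returns (module, co-matching modules).
    """
    if registry is None:
        registry = load_module_registry()
    accessions = {
        h.accession for h in domain_hits if h.locus_tag == locus_tag
    }
    return registry.classify(accessions)


def attach_canonical_modules(calls: Iterable[ReceptorCall]) -> list[ReceptorCall]:
    """Fill canonical modules for LuxP, LsrB and GAPES1 calls."""
    out = []
    for call in calls:
        module = CANONICAL_MODULES.get(call.receptor_type)
        if module is not None and call.functional_module is None:
            call = replace(call, functional_module=module)
        out.append(call)
    return out


def assign_modules(
    calls: Iterable[ReceptorCall],
    full_scan_hits: Iterable[DomainHit],
    registry: ModuleRegistry | None = None,
) -> list[ReceptorCall]:
    """Attach modules to every receptor call.

    dCache_1 calls are classified from their protein's full-protein domain
    scan; LuxP/LsrB/GAPES1 get their canonical modules.  Co-matching
    modules are recorded in the call evidence.
    """
    if registry is None:
        registry = load_module_registry()
    hits_by_locus: dict[tuple[str, str], list[DomainHit]] = {}
    for hit in full_scan_hits:
        hits_by_locus.setdefault((hit.genome_id, hit.locus_tag), []).append(hit)

    out = []
    for call in attach_canonical_modules(calls):
        if call.receptor_type == "dCache_1":
            hits = hits_by_locus.get((call.genome_id, call.locus_tag), [])
            module, matching = classify_architecture(
                call.locus_tag, hits, registry)
            evidence = dict(call.evidence)
            evidence["matching_modules"] = matching
            call = replace(call, functional_module=module, evidence=evidence)
        out.append(call)
    return out


def module_census(
    calls: Iterable[ReceptorCall],
    genomes: Iterable[SpeciesGenome],
) -> tuple[pd.DataFrame, dict[str, Counter]]:
    """Module x phylum species counts plus the per-species module multiset.

    The species count table counts each species once per module it carries;
    the multiset preserves gene-level multiplicity.
    """
    phylum_of = {g.genome_id: g.taxonomy.phylum for g in genomes}
    per_species: dict[str, Counter] = {}
    for call in calls:
        module = call.functional_module or UNCHARACTERIZED
        per_species.setdefault(call.genome_id, Counter())[module] += 1

    cells: Counter = Counter()
    for genome_id, modules in per_species.items():
        phylum = phylum_of.get(genome_id, "")
        for module in modules:
            cells[(module, phylum)] += 1
    if not cells:
        return pd.DataFrame(), {}
    table = pd.Series(cells).unstack(fill_value=0)
    table.index.name = "module"
    table.columns.name = "phylum"
    return table.sort_index().sort_index(axis=1), per_species
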