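"""Curated gene-set catalog for acid/base-transporting SLCs (ABT-SLCs).

The built-in catalog holds the 27 ABT-SLC genes split into four functional
sub-groups by the type of acid/base flux carried:

* MCT — monocarboxylate (lactate/H+) transporters, SLC16 family;
* NHE — sodium-hydrogen exchangers, SLC9 family;
* NBC — sodium-bicarbonate cotransporters, SLC4 family (Na+-coupled);
* AE  — anion (Cl-/HCO3-) exchangers, SLC4 and SLC26 families.

Comparator SLC groups (glucose, amino-acid, nucleoside/nucleotide
transporters) used to contextualise the ranking analysis are also provided;
their membership follows the standard HGNC family assignments and can be
overridden from a YAML/JSON config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError

ABT_GROUPS: dict = {
    "MCT": ("SLC16A1", "SLC16A3", "SLC16A7", "SLC16A8"),
    "AE": ("SLC4A1", "SLC4A2", "SLC4A3", "SLC4A9",
           "SLC26A3", "SLC26A4", "SLC26A6", "SLC26A9"),
    "NBC": ("SLC4A4", "SLC4A5", "SLC4A7", "SLC4A8", "SLC4A10"),
    "NHE": ("SLC9A1", "SLC9A2", "SLC9A3", "SLC9A5", "SLC9A6",
            "SLC9A7", "SLC9A8", "SLC9A9", "SLC9B2", "SLC9C1"),
}

ABT_ROLES: dict = {
    "MCT": "acid-extruder (fermentive cells)",
    "AE": "acid-loader",
    "NBC": "acid-extruder (except SLC4A5)",
    "NHE": "acid-extruder",
}

#: Comparator SLC groups by HGNC family; overridable via load_gene_sets.
COMPARATOR_GROUPS: dict = {
    "glucose": tuple(f"SLC2A{i}" for i in range(1, 15)),
    "amino_acid": (
        "SLC1A1", "SLC1A2", "SLC1A3", "SLC1A4", "SLC1A5", "SLC1A6", "SLC1A7",
        "SLC7A1", "SLC7A2", "SLC7A3", "SLC7A5", "SLC7A6", "SLC7A7", "SLC7A8",
        "SLC7A9", "SLC7A10", "SLC7A11", "SLC7A13", "SLC7A14",
        "SLC6A5", "SLC6A7", "SLC6A9", "SLC6A14", "SLC6A15", "SLC6A17",
        "SLC6A18", "SLC6A19", "SLC6A20",
        "SLC38A1", "SLC38A2", "SLC38A3", "SLC38A4", "SLC38A5", "SLC38A6",
        "SLC38A7", "SLC38A8", "SLC38A9", "SLC38A10", "SLC38A11",
    ),
    "nucleoside": ("SLC28A1", "SLC28A2", "SLC28A3",
                   "SLC29A1", "SLC29A2", "SLC29A3", "SLC29A4"),
}

_ABT_GROUP_NAMES = tuple(ABT_GROUPS)


@dataclass
class GeneSetCatalog:
    """Named gene groups with membership maps.

    Within the ABT catalog the four sub-groups are disjoint and union to
    exactly 27 genes; comparator groups may overlap each other (but not
    internally repeat a symbol).
    """

    groups: dict  # group name -> tuple of gene symbols (ordered)
    roles: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, genes in self.groups.items():
            genes = tuple(genes)
            if len(set(genes)) != len(genes):
                raise ConfigurationError(f"group '{name}' repeats a symbol")
            if not genes:
                raise ConfigurationError(f"group '{name}' is empty")
            self.groups[name] = genes
        abt = [g for g in _ABT_GROUP_NAMES if g in self.groups]
        seen: set = set()
        for name in abt:
            overlap = seen & set(self.groups[name])
            if overlap:
                raise ConfigurationError(
                    f"ABT sub-groups must be disjoint; '{name}' shares {sorted(overlap)}")
            seen |= set(self.groups[name])

    def genes(self, group: str) -> tuple:
        try:
            return self.groups[group]
        except KeyError:
            raise ConfigurationError(f"unknown gene group '{group}'") from None

    def all_genes(self) -> tuple:
        out, seen = [], set()
        for genes in self.groups.values():
            for g in genes:
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return tuple(out)

    def abt_genes(self) -> tuple:
        out = []
        for name in _ABT_GROUP_NAMES:
            out.extend(self.groups.get(name, ()))
        return tuple(out)

    def abt_groups(self) -> dict:
        return {n: self.groups[n] for n in _ABT_GROUP_NAMES if n in self.groups}

    def membership(self, symbol: str) -> "str | None":
        """Group of ``symbol`` among the ABT sub-groups (None if ungrouped)."""
        for name in _ABT_GROUP_NAMES:
            if symbol in self.groups.get(name, ()):
                return name
        return None


def builtin_abt_catalog(include_comparators: bool = True) -> GeneSetCatalog:
    """The built-in 27-gene ABT-SLC catalog (plus comparator SLC groups)."""
    groups = {k: v for k, v in ABT_GROUPS.items()}
    if include_comparators:
        groups.update(COMPARATOR_GROUPS)
    return GeneSetCatalog(groups, roles=dict(ABT_ROLES),
                          provenance=["builtin_abt_catalog"])


def load_gene_sets(path) -> GeneSetCatalog:
    """Load a user catalog (YAML or JSON mapping group -> list of symbols),
    merged over the builtins.  Redefining a built-in group overrides it and
    the override is recorded in provenance."""
    with open(path) as fh:
        text = fh.read()
    try:
        user = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text))
    except Exception as exc:
        raise ConfigurationError(f"cannot parse gene-set file {path}: {exc}") from exc
    if not isinstance(user, dict) or not user:
        raise ConfigurationError(f"{path}: expected a mapping of group -> gene list")

    cat = builtin_abt_catalog()
    provenance = [*cat.provenance, f"load_gene_sets({path})"]
    groups = dict(cat.groups)
    for name, genes in user.items():
        if not genes:
            raise ConfigurationError(f"{path}: group '{name}' is empty")
        if name in groups:
            provenance.append(f"override of builtin group '{name}'")
        groups[name] = tuple(str(g) for g in genes)
    return GeneSetCatalog(groups, roles=dict(cat.roles), provenance=provenance)


def save_gene_sets(catalog: GeneSetCatalog, path) -> None:
    """Write a catalog as YAML (loadable by :func:`load_gene_sets`)."""
    data = {name: list(genes) for name, genes in catalog.groups.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def export_catalog_tsv(catalog: GeneSetCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("group\tgene\trole\n")
        for name, genes in catalog.groups.items():
            role = catalog.roles.get(name, "")
            for g in genes:
                fh.write(f"{name}\t{g}\t{role}\n")
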