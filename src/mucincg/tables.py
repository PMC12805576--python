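"""Loading of the packaged parameter tables (bead types, templates, LJ).

All tables ship as human-readable YAML under ``mucincg/data`` and can be
overridden by passing a path to the corresponding loader.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .core import BeadType, NonbondedParams
from .mapper import AttachmentRule, BeadTemplate, MappingSpec, ResidueTemplate

__all__ = [
    "load_bead_types",
    "load_mapping_spec",
    "default_mapping_spec",
    "load_lj_table",
    "load_mini2_composition",
]


def _read_yaml(name: str, path: str | Path | None) -> dict:
    if path is not None:
        return yaml.safe_load(Path(path).read_text())
    return yaml.safe_load(
        resources.files("mucincg.data").joinpath(name).read_text()
    )


def load_bead_types(path: str | Path | None = None) -> dict[str, BeadType]:
    """Bead chemotype table: name -> BeadType (radius/mass from size class)."""
    raw = _read_yaml("bead_types.yaml", path)
    out = {}
    for name, entry in raw["bead_types"].items():
        out[name] = BeadType(
            name=name,
            size_class=entry["size_class"],
            charge=int(entry.get("charge", 0)),
            vdw_radius=entry.get("vdw_radius"),
            mass=entry.get("mass"),
        )
    return out


def load_mapping_spec(path: str | Path | None = None,
                      bead_types: dict[str, BeadType] | None = None) -> MappingSpec:
    """Residue-template mapping spec (protein + O-glycan sugar templates)."""
    raw = _read_yaml("residue_templates.yaml", path)
    if bead_types is None:
        bead_types = load_bead_types()
    templates: dict[str, ResidueTemplate] = {}
    for category, key in (("protein", "protein"), ("sugar", "sugars")):
        for resname, tpl in raw.get(key, {}).items():
            beads = tuple(
                BeadTemplate(
                    name=b["name"],
                    type_name=b["type"],
                    atoms=tuple(b["atoms"]),
                    ring=bool(b.get("ring", False)),
                    optional=tuple(b.get("optional", ())),
                )
                for b in tpl["beads"]
            )
            templates[resname] = ResidueTemplate(
                resname=resname,
                beads=beads,
                intra_bonds=tuple(tuple(p) for p in tpl.get("intra_bonds", ())),
                category=category,
                anomeric_bead=tpl.get("anomeric_bead"),
                anomeric_oh=tpl.get("anomeric_oh"),
                hexnac=bool(tpl.get("hexnac", False)),
                acceptor_atom=tpl.get("acceptor_atom"),
            )
    attachment = {
        res: AttachmentRule(side_bead=r["side_bead"], link_type=r["link_type"],
                            link_atom=r["link_atom"])
        for res, r in raw.get("attachment", {}).items()
    }
    return MappingSpec(
        templates=templates,
        bead_types=bead_types,
        attachment=attachment,
        donor_retype=dict(raw.get("donor_retype",
                                  {"hexnac": "TC5", "default": "TN6"})),
        bonded_defaults={k: dict(v) for k, v in raw.get("bonded_defaults", {}).items()}
        or MappingSpec.__dataclass_fields__["bonded_defaults"].default_factory(),
    )


def default_mapping_spec() -> MappingSpec:
    return load_mapping_spec()


def load_lj_table(path: str | Path | None = None) -> NonbondedParams:
    """Pairwise LJ table expanded from per-size-class sigmas.

    sigma(i,j) is the arithmetic mean of the class sigmas; a single generic
    epsilon is used for every pair (sufficient for bookkeeping and rescaling;
    engine-grade interaction matrices should be supplied by the user).
    """
    raw = _read_yaml("bead_types.yaml", path)
    types = load_bead_types(path)
    sigma = raw["lj"]["sigma"]
    eps = float(raw["lj"]["epsilon_default"])
    group_of: dict[str, str] = {}
    for group, members in raw["groups"].items():
        for m in members:
            group_of[m] = group
    names = sorted(types)
    table = {}
    for i, a in enumerate(names):
        for b in names[i:]:
            s = 0.5 * (sigma[types[a].size_class] + sigma[types[b].size_class])
            table[(a, b)] = (s, eps)
    return NonbondedParams(table, group_of)


def load_mini2_composition(path: str | Path | None = None) -> dict:
    """Synthetic Mini2 construct composition (sequence, sites, glycan trees)."""
    return _read_yaml("mini2_synthetic.yaml", path)
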