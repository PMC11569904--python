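"""Hierarchical criteria tree: domains, criteria, subcriteria.

The evaluation hierarchy has three nested levels. *Domains* partition the
decision problem; each domain contains *criteria*; a criterion may contain
*subcriteria*. The leaves of the tree — every subcriterion, plus every
criterion without subcriteria — are the units that receive technology
scores. Node identifiers are positional tokens (``d1``, ``d1.c2``,
``d1.c2.s1``) so that survey files, weight tables, and score sheets join on
stable keys while labels carry the human meaning.

Configuration lives in a YAML (or JSON) file::

    name: my-framework
    version: "1.0"
    domains:
      - id: d1
        label: Need for intervention
        description: ...
        criteria:
          - id: d1.c1
            label: Affected population
            subcriteria:
              - id: d1.c1.s1
                label: Disease incidence

Document order is preserved everywhere and is the canonical tie-breaking
order downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional

import yaml

#: Sentinel group id for the top-level question (allocating points among domains).
ROOT_GROUP = "root"

LEVELS = ("domain", "criterion", "subcriterion")


class CriteriaConfigError(ValueError):
    """Raised when a criteria configuration cannot be parsed or is invalid."""

    def __init__(self, message: str, report: Optional["ValidationReport"] = None):
        super().__init__(message)
        self.report = report


@dataclass
class CriterionNode:
    """One node of the hierarchy.

    Parameters
    ----------
    node_id : str
        Short stable token, unique across the tree.
    label : str
        Human-readable name.
    level : {"domain", "criterion", "subcriterion"}
    parent_id : str or None
        Enclosing node; ``None`` for domains.
    description : str
        Glossary text shown to respondents/users.
    children : list of str
        Ordered child node ids (empty for subcriteria).
    placeholder : bool
        True for stand-in nodes whose label is not a validated criterion.
    """

    node_id: str
    label: str
    level: str
    parent_id: Optional[str] = None
    description: str = ""
    children: list[str] = field(default_factory=list)
    placeholder: bool = False


@dataclass
class ValidationReport:
    """Outcome of structural validation: ``ok`` iff ``violations`` is empty."""

    violations: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, node: str, rule: str, message: str) -> None:
        self.violations.append((node, rule, message))

    def __str__(self) -> str:
        if self.ok:
            return "OK: tree is valid"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  [{rule}] {node}: {msg}" for node, rule, msg in self.violations]
        return "\n".join(lines)


@dataclass
class CriteriaTree:
    """A validated three-level hierarchy with an id index.

    Use :func:`load_criteria_config` / :func:`load_default_tree` to build one.
    """

    name: str
    version: str
    domains: list[str]
    index: dict[str, CriterionNode]

    def node(self, node_id: str) -> CriterionNode:
        return self.index[node_id]

    def children(self, node_id: str) -> list[str]:
        """Child ids of ``node_id``; the domains for :data:`ROOT_GROUP`."""
        if node_id == ROOT_GROUP:
            return list(self.domains)
        return list(self.index[node_id].children)

    def nodes_at_level(self, level: str) -> list[str]:
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
        return [n for n in self.iter_ids() if self.index[n].level == level]

    def iter_ids(self) -> Iterator[str]:
        """All node ids in document order (depth-first)."""
        for d in self.domains:
            yield d
            for c in self.index[d].children:
                yield c
                yield from self.index[c].children

    def sibling_groups(self) -> list[str]:
        """Group ids with ≥1 child: ROOT_GROUP, domains, criteria with subcriteria."""
        groups = [ROOT_GROUP]
        groups += [d for d in self.domains if self.index[d].children]
        for d in self.domains:
            groups += [c for c in self.index[d].children if self.index[c].children]
        return groups

    def leaves(self) -> list[str]:
        """Leaf ids (subcriteria plus subcriterion-less criteria), document order."""
        return list(self._iter_leaves())

    def _iter_leaves(self) -> Iterator[str]:
        for d in self.domains:
            for c in self.index[d].children:
                subs = self.index[c].children
                if subs:
                    yield from subs
                else:
                    yield c

    def path_to(self, node_id: str) -> list[str]:
        """Ids from the domain down to ``node_id`` inclusive."""
        path = []
        cur: Optional[str] = node_id
        while cur is not None:
            path.append(cur)
            cur = self.index[cur].parent_id
        return path[::-1]


def _parse_node(raw: dict, level: str, parent_id: Optional[str], where: str) -> CriterionNode:
    if not isinstance(raw, dict):
        raise CriteriaConfigError(f"{where}: expected a mapping, got {type(raw).__name__}")
    try:
        node_id = str(raw["id"])
        label = str(raw["label"])
    except KeyError as exc:
        raise CriteriaConfigError(f"{where}: missing required field {exc.args[0]!r}") from exc
    return CriterionNode(
        node_id=node_id,
        label=label,
        level=level,
        parent_id=parent_id,
        description=str(raw.get("description", "")).strip(),
        placeholder=bool(raw.get("placeholder", False)),
    )


def _tree_from_mapping(data: dict, source: str = "<config>") -> CriteriaTree:
    if not isinstance(data, dict):
        raise CriteriaConfigError(f"{source}: top level must be a mapping")
    for key in ("name", "domains"):
        if key not in data:
            raise CriteriaConfigError(f"{source}: missing required field {key!r}")
    index: dict[str, CriterionNode] = {}
    order: list[tuple[str, CriterionNode]] = []  # (id, node) in document order, dup-tolerant
    domains: list[str] = []
    for i, rawd in enumerate(data["domains"] or []):
        dnode = _parse_node(rawd, "domain", None, f"{source}: domains[{i}]")
        domains.append(dnode.node_id)
        order.append((dnode.node_id, dnode))
        for j, rawc in enumerate(rawd.get("criteria") or []):
            cnode = _parse_node(rawc, "criterion", dnode.node_id, f"{source}: {dnode.node_id}.criteria[{j}]")
            dnode.children.append(cnode.node_id)
            order.append((cnode.node_id, cnode))
            for k, raws in enumerate(rawc.get("subcriteria") or []):
                snode = _parse_node(raws, "subcriterion", cnode.node_id, f"{source}: {cnode.node_id}.subcriteria[{k}]")
                cnode.children.append(snode.node_id)
                order.append((snode.node_id, snode))
    for node_id, node in order:
        if node_id not in index:  # duplicates surface via validate_tree's traversal
            index[node_id] = node
    tree = CriteriaTree(
        name=str(data["name"]),
        version=str(data.get("version", "")),
        domains=domains,
        index=index,
    )
    report = validate_tree(tree)
    if not report.ok:
        raise CriteriaConfigError(f"{source}: invalid criteria tree\n{report}", report=report)
    return tree


def load_criteria_config(path: str | Path) -> CriteriaTree:
    """Load and validate a criteria tree from a YAML or JSON file.

    Raises
    ------
    CriteriaConfigError
        On parse failure (naming the file) or on any structural-invariant
        breach (listing *all* violations, not just the first).
    """
    path = Path(path)
    if not path.exists():
        raise CriteriaConfigError(f"criteria config not found: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise CriteriaConfigError(f"{path}: cannot parse configuration: {exc}") from exc
    return _tree_from_mapping(data, source=str(path))


def load_default_tree() -> CriteriaTree:
    """The packaged default framework: 5 domains, 15 criteria, 15 subcriteria."""
    ref = resources.files("mcda_hta.data").joinpath("default_criteria.yaml")
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _tree_from_mapping(data, source="packaged default")


def tree_to_mapping(tree: CriteriaTree) -> dict:
    """Inverse of the config schema: a plain mapping that round-trips."""

    def node_dict(node: CriterionNode) -> dict:
        d: dict = {"id": node.node_id, "label": node.label}
        if node.description:
            d["description"] = node.description
        if node.placeholder:
            d["placeholder"] = True
        return d

    out: dict = {"name": tree.name, "version": tree.version, "domains": []}
    for did in tree.domains:
        dd = node_dict(tree.index[did])
        crits = []
        for cid in tree.index[did].children:
            cd = node_dict(tree.index[cid])
            subs = [node_dict(tree.index[sid]) for sid in tree.index[cid].children]
            if subs:
                cd["subcriteria"] = subs
            crits.append(cd)
        if crits:
            dd["criteria"] = crits
        out["domains"].append(dd)
    return out


def write_criteria_config(tree: CriteriaTree, path: str | Path) -> None:
    """Serialize a tree back to YAML (or JSON if the suffix is ``.json``)."""
    path = Path(path)
    data = tree_to_mapping(tree)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
    else:
        path.write_text(
            yaml.safe_dump(data, sort_keys=False, allow_unicode=True, width=88),
            encoding="utf-8",
        )


def validate_tree(tree: CriteriaTree) -> ValidationReport:
    """Check every structural invariant; violations are the report's content.

    Rules: ``unique-id`` (ids unique), ``nonempty`` (≥1 domain, leaves exist),
    ``parent-link`` (parent/child ids resolve and agree), ``level-nesting``
    (domain→criterion→subcriterion), ``leaf-level`` (subcriteria childless),
    ``root-parent`` (domains parentless, others parented).
    """
    report = ValidationReport()
    if not tree.domains:
        report.add("<tree>", "nonempty", "tree has no domains")
        return report
    seen: set[str] = set()
    for nid in tree.iter_ids():
        if nid in seen:
            report.add(nid, "unique-id", f"node_id {nid!r} appears more than once")
        seen.add(nid)
        if nid not in tree.index:
            report.add(nid, "parent-link", "child id not present in index")
            continue
        node = tree.index[nid]
        if node.level not in LEVELS:
            report.add(nid, "level-nesting", f"unknown level {node.level!r}")
            continue
        if node.level == "domain":
            if node.parent_id is not None:
                report.add(nid, "root-parent", "domain must not have a parent")
            bad = [c for c in node.children if c in tree.index and tree.index[c].level != "criterion"]
            for c in bad:
                report.add(nid, "level-nesting", f"child {c!r} of a domain is not a criterion")
        elif node.level == "criterion":
            if node.parent_id is None:
                report.add(nid, "root-parent", "criterion must have a parent domain")
            elif node.parent_id in tree.index and tree.index[node.parent_id].level != "domain":
                report.add(nid, "level-nesting", "parent of a criterion must be a domain")
            bad = [c for c in node.children if c in tree.index and tree.index[c].level != "subcriterion"]
            for c in bad:
                report.add(nid, "level-nesting", f"child {c!r} of a criterion is not a subcriterion")
        else:  # subcriterion
            if node.parent_id is None:
                report.add(nid, "root-parent", "subcriterion must have a parent criterion")
            if node.children:
                report.add(nid, "leaf-level", "subcriterion must not have children")
        for c in node.children:
            if c not in tree.index:
                report.add(nid, "parent-link", f"child {c!r} missing from index")
            elif tree.index[c].parent_id != nid:
                report.add(c, "parent-link", f"parent_id {tree.index[c].parent_id!r} != enclosing node {nid!r}")
    if not list(tree._iter_leaves()):
        report.add("<tree>", "nonempty", "tree has no leaves")
    return report


def leaf_paths(tree: CriteriaTree) -> list[tuple[str, str, Optional[str]]]:
    """``(domain_id, criterion_id, subcriterion_id-or-None)`` per leaf, in document order.

    Criteria without subcriteria are themselves leaves and appear with the
    third slot ``None``.
    """
    paths: list[tuple[str, str, Optional[str]]] = []
    for did in tree.domains:
        for cid in tree.index[did].children:
            subs = tree.index[cid].children
            if subs:
                paths.extend((did, cid, sid) for sid in subs)
            else:
                paths.append((did, cid, None))
    return paths
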