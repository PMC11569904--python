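import numpy as np
import pytest

from mcda_hta import (
    AllocationRecord,
    AllocationSet,
    CriteriaTree,
    CriterionNode,
    load_default_tree,
)
from mcda_hta.tree import _tree_from_mapping


@pytest.fixture(scope="session")
def default_tree() -> CriteriaTree:
    return load_default_tree()


def make_tree(layout: dict, name: str = "test-tree") -> CriteriaTree:
    """Build a tree from a {domain_label: {criterion_label: [sub_labels]}}."""
    domains = []
    for i, (dlabel, crits) in enumerate(layout.items(), 1):
        did = f"d{i}"
        criteria = []
        for j, (clabel, subs) in enumerate(crits.items(), 1):
            cid = f"{did}.c{j}"
            entry = {"id": cid, "label": clabel}
            if subs:
                entry["subcriteria"] = [
                    {"id": f"{cid}.s{k}", "label": slabel}
                    for k, slabel in enumerate(subs, 1)
                ]
            criteria.append(entry)
        domains.append({"id": did, "label": dlabel, "criteria": criteria})
    return _tree_from_mapping({"name": name, "version": "1", "domains": domains})


@pytest.fixture
def tiny_tree() -> CriteriaTree:
    """One domain, one criterion, no subcriteria: the degenerate hierarchy."""
    return make_tree({"Only domain": {"Only criterion": []}})


@pytest.fixture
def two_domain_tree() -> CriteriaTree:
    """Two domains with one subcriterion-less criterion each."""
    return make_tree({"First": {"C1": []}, "Second": {"C2": []}})


def random_tree(rng: np.random.Generator, max_domains=5, max_crit=4, max_sub=4) -> CriteriaTree:
    layout: dict = {}
    for i in range(rng.integers(1, max_domains + 1)):
        crits: dict = {}
        for j in range(rng.integers(1, max_crit + 1)):
            n_sub = int(rng.integers(0, max_sub + 1))
            crits[f"crit {i}.{j}"] = [f"sub {i}.{j}.{k}" for k in range(n_sub)]
        layout[f"domain {i}"] = crits
    return make_tree(layout, name="random")


def allocation_set(tree: CriteriaTree, allocations: dict) -> AllocationSet:
    """Build an AllocationSet from {sample: {respondent: {group: {node: pts}}}}."""
    allocs = AllocationSet(tree=tree)
    for sample_id, by_resp in allocations.items():
        for rid, by_group in by_resp.items():
            for gid, points in by_group.items():
                allocs.add(AllocationRecord(
                    respondent_id=rid, sample_id=sample_id,
                    group_id=gid, points=dict(points),
                ))
    return allocs
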