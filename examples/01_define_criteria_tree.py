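"""Load and inspect the packaged criteria hierarchy.

The evaluation framework is a three-level tree: five domains, fifteen
criteria, fifteen subcriteria. Leaves (every subcriterion plus every
criterion without subcriteria) are the units that receive technology scores.
"""

from mcda_hta import leaf_paths, load_default_tree, validate_tree

tree = load_default_tree()
report = validate_tree(tree)
print(f"tree {tree.name!r} v{tree.version}: {report}")
print(f"{len(tree.domains)} domains, "
      f"{len(tree.nodes_at_level('criterion'))} criteria, "
      f"{len(tree.nodes_at_level('subcriterion'))} subcriteria, "
      f"{len(tree.leaves())} leaves\n")

for did in tree.domains:
    dom = tree.index[did]
    print(f"{did}  {dom.label}")
    for cid in dom.children:
        crit = tree.index[cid]
        flag = " [placeholder]" if crit.placeholder else ""
        print(f"  {cid}  {crit.label}{flag}")
        for sid in crit.children:
            sub = tree.index[sid]
            sflag = " [placeholder]" if sub.placeholder else ""
            print(f"    {sid}  {sub.label}{sflag}")

print("\nleaf paths (domain, criterion, subcriterion-or-None):")
for path in leaf_paths(tree)[:6]:
    print(" ", path)
print(f"  ... {len(leaf_paths(tree))} leaves in total")
# Each leaf's composite-value weight is the product of the normalized
# weights along its path; the products sum to one over all leaves.
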