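"""The chemokine roster: subfamilies, ELR+ ligands, receptor pairing,
mouse orthologs."""

from chemoatlas import build_default_registry, map_to_mouse

registry = build_default_registry()
print(f"{len(registry.ligands)} ligands, {len(registry.receptors)} receptors")

record = registry.lookup("CXCL7")  # alias of PPBP
print(f"CXCL7 resolves to {record.symbol}, family {record.family}, "
      f"ELR+ = {record.elr_positive}")

elr = [r.symbol for r in registry.ligands if r.elr_positive]
print(f"ELR+ ligands (bind CXCR1/CXCR2): {', '.join(elr)}")

mapping, unmapped = map_to_mouse(registry, ["CCL2", "CXCL8", "CXCL12"])
print(f"mouse orthologs: {mapping}; no ortholog: {unmapped}")
# CXCL8 is reported unmapped because the mouse genome has no IL-8 gene —
# cross-species comparisons silently lose it, which matters downstream.
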