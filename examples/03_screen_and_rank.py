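"""End-to-end screen: patches -> residue contributions -> mutation design ->
min-max triage ranking.

A toy structure with one dominant hydrophobic cluster is screened; the
mutation enumerator proposes patch-disrupting substitutions (hydrophobic
residues to L/Q, K/R to E/G, D->N / E->Q) at the top patch-contributing
residues, each candidate's patches are recomputed on a naive Cβ-truncated
mutant model, and the panel is ranked by the summed min-max normalised
score (lower = less predicted viscosity risk). The winner should be a W->Q
substitution inside the designed cluster.
"""

import patchscreen as ps

spec = ps.PatchSpec(
    clusters=(ps.ClusterSpec("hydrophobic", 8), ps.ClusterSpec("positive", 5)),
    n_residues=60,
    seed=3,
)
model, designed = ps.make_toy_structure(spec)

config = ps.RunConfig(out_dir="scratch/example_screen", top_n=3)
outputs = ps.run_screen(config, model=model)

print("candidate panel:")
print(outputs["candidates"].to_string(index=False))
print("\nranked panel (ascending score = most developable first):")
print(outputs["ranked_panel"].head(6).to_string(index=False))

top = outputs["ranked_panel"].iloc[0]
desc = outputs["descriptors"].set_index("variant_id")
print(
    f"\ntop candidate {top['variant_id']}: hydrophobic area "
    f"{desc.loc[top['variant_id'], 'hyd_area_A2']:.1f} Å² vs WT "
    f"{desc.loc['WT', 'hyd_area_A2']:.1f} Å²"
)
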