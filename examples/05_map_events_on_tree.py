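"""Place gene-order changes on a species tree by Fitch parsimony.

The gene order of each sampled individual is an unordered multistate
character; the minimum number of state changes gives the number of
independent rearrangement events, and the reported placements locate them
on branches.  A species polymorphic for gene order contributes one tip per
individual.
"""

from mitodrl import fitch_min_changes, polymorphic_species_expand
from mitodrl.phylo_events import PhyloTree

newick = (
    "((Desmognathus_fuscus,Plethodon_elongatus,Ensatina_eschscholtzii,"
    "Hydromantes_brunus),(aeneus,((hardii_RAC20,hardii_RAC25,hardii_RAC42,"
    "hardii_RAC54),(lugubris,(flavipunctatus,(ferreus,vagrans))))));"
)
tree = PhyloTree.from_newick(newick, outgroup="Desmognathus_fuscus")

states_by_individual = {
    "hardii_RAC20": "derived_duplicated",
    "hardii_RAC25": "derived_duplicated",
    "hardii_RAC42": "genus_order",
    "hardii_RAC54": "genus_order",
}
species = {k: "hardii" for k in states_by_individual}
print("polymorphic species expansion:",
      polymorphic_species_expand(states_by_individual, species))

tip_states = {
    t: "typical_vertebrate"
    for t in ("Desmognathus_fuscus", "Plethodon_elongatus",
              "Ensatina_eschscholtzii", "Hydromantes_brunus")
}
for t in ("aeneus", "lugubris", "flavipunctatus", "ferreus", "vagrans",
          "hardii_RAC42", "hardii_RAC54"):
    tip_states[t] = "genus_order"
tip_states["hardii_RAC20"] = "derived_duplicated"
tip_states["hardii_RAC25"] = "derived_duplicated"

result = fitch_min_changes(tree, tip_states)
print(f"minimum rearrangement events: {result.min_changes} "
      f"({result.n_mprs} most-parsimonious reconstructions)")
for p in result.placements:
    print(f"  {p.edge[0]} -> {p.edge[1]}: {p.from_state} => {p.to_state}")
# Two events: one on the stem of the genus, one inside the polymorphic
# species.
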