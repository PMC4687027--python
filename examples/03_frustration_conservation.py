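"""Sequence vs frustration conservation over a synthetic repeat family.

Builds a family of eight solenoids sharing a consensus in which a core of
positions is nearly fixed while the rest mutate freely, aligns all repeats
structurally, and compares per-position sequence information content with
the information content of single-residue frustration states. Conserved
hydrophobic positions stay minimally frustrated in every member, so the two
profiles correlate. The canonical contact map then locates the conserved
minimally-frustrated interactions within and between repeats.
"""

import numpy as np

from solentile import (
    SolenoidSpec,
    build_struct_msa,
    canonical_contact_map,
    chain_contact_frustration,
    chain_residue_frustration,
    conserved_network,
    extract_fragment,
    frustration_ic,
    ic_correlation,
    make_family,
    sequence_ic,
)

conserved = [0, 4, 5, 6, 7, 8, 9, 10, 11, 19, 20, 23, 24, 32]
rates = np.full(33, 0.8)
rates[conserved] = 0.02
family = make_family(
    SolenoidSpec(n_units=6, noise_sd=0.3, position_mutation_rates=rates,
                 seed=100),
    8,
)

model0, truth0 = family[0]
s, e = truth0.unit_boundaries[2]
query = extract_fragment(model0, "A", s, e - s)
msa, arrays = build_struct_msa(query, [(m, "A") for m, _ in family], 33)
seq_prof = sequence_ic(msa)

observations = [[] for _ in range(33)]
for (model, _), array in zip(family, arrays):
    residue_records = chain_residue_frustration(model, "A")
    for unit in array.units:
        for t_idx, c in unit.canonical_map.items():
            observations[c - 1].append(residue_records[t_idx].klass)
frust_prof = frustration_ic(observations)

r, p, n = ic_correlation(seq_prof, frust_prof)
print(f"sequence IC vs frustration IC over {n} canonical positions:")
print(f"  Pearson r = {r:.3f}, p = {p:.2e}")
print("  (conserved positions are both sequence-fixed and consistently")
print("   minimally frustrated, so the two conservation measures agree)")

entries = []
for (model, _), array in zip(family, arrays):
    contact_records = chain_contact_frustration(model, "A", seed=1)
    entries.append((array, contact_records))
cmap = canonical_contact_map(entries, period=33)
net = conserved_network(cmap)
print(f"\ncanonical contact map over {cmap.n_pairs} internal repeat pairs:")
print(f"  {len(cmap.cells)} canonical contacts observed")
print(f"  conserved-interaction network threshold (highest neutral-dominant "
      f"IC): {net.threshold:.3f} bits")
print(f"  {len(net.intra())} conserved interactions within a repeat, "
      f"{len(net.inter())} between adjacent repeats")
print("\nmost conserved minimally-frustrated contacts "
      "(state, frequency, weighted IC):")
top = sorted(
    (c for c in cmap.cells.values() if c.most_informative == "MINIMAL"),
    key=lambda c: -c.weighted_ic,
)[:8]
for cell in top:
    a, b = cell.pair
    tag = "intra" if cmap.is_intra(cell.pair) else "inter"
    print(f"  ({a:2d},{b:2d}) {tag}  {cell.most_informative:8s} "
          f"freq={cell.frequency:.2f}  IC={cell.weighted_ic:.3f} bits")
print("\nIn this idealized family the geometry is identical in every member,")
print("so some contacts are perfectly conserved in the neutral state and the")
print("threshold saturates at log2(3); real families leave neutral-dominant")
print("contacts noisier and the network picks out the stabilizing core.")
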