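"""Flanking-base composition and degenerate-motif discovery.

Extracts the +-4 bp context of every 6mA site (strand-aware, 5'->3' on the
methylated strand), summarizes per-position base frequencies, and scans for
enriched k-mers (k = 5..7) against a background of unmethylated adenines.
The generator biases half the sites toward an AGG context, so an AGG-core
consensus should rank first.
"""

import m6atlas as m

bundle = m.generate(m.SyntheticConfig(seed=1))
table = m.filter_by_coverage(bundle.records, 25)

flanks = m.extract_flanks(table, bundle.genome)
comp = m.composition(flanks).set_index("position")
print("base frequencies around the methylated A (position 0):")
print(comp[list("ACGT")].round(3).to_string())
print(f"\nG at +1: {comp.loc[1, 'G']:.1%}, G at +2: {comp.loc[2, 'G']:.1%} "
      "(elevated by the planted AGG context)")

background = m.sample_background_flanks(bundle.genome, table, 10 * len(flanks), seed=1)
candidates = m.find_motifs(flanks, background)
print("\ntop motif candidates (consensus, methyl-A offset, E-value, fraction of sites):")
for c in candidates[:5]:
    print(f"  {c.consensus:<8} offset={c.offset}  E={c.e_value:.3g}  fraction={c.fraction:.2f}")
top = candidates[0]
print(f"\nrank-1 consensus {top.consensus!r} carries the methylated A at index "
      f"{top.offset} followed by GG — the planted core.")
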