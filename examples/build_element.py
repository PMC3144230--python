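"""Build the synthetic Tc1/mariner-like consensus element and recover its
structure with the annotation tools.

The generator plants the canonical architecture — 1,581 bp total, 199-bp
terminal inverted repeats (IRs) each carrying a 17-bp direct repeat (DR), a
transposase ORF and a polyadenylation signal — and the detectors must get the
same numbers back from the bare sequence.
"""

from tc1scope import (
    ElementArchitecture,
    build_consensus_element,
    detect_direct_repeats,
    detect_terminal_inverted_repeats,
)

consensus = build_consensus_element(ElementArchitecture(seed=1))
print(f"element: {consensus.id}, {len(consensus)} bp")
print(f"ORF: {consensus.orf_interval[0] + 1}..{consensus.orf_interval[1]} "
      f"({consensus.orf_interval[1] - consensus.orf_interval[0]} nt)")
print(f"PAS at {consensus.pas_interval[0] + 1}..{consensus.pas_interval[1]}")

ir = detect_terminal_inverted_repeats(consensus.sequence, min_len=30, min_identity=95)
print(f"detected IR: {ir.length} bp at both termini, {ir.percent_identity:.1f}% identity")

for d in detect_direct_repeats(consensus.sequence, ir, k=12):
    print(f"detected DR: {d.length} bp at {d.left[0] + 1}..{d.left[1]} and {d.right[0] + 1}..{d.right[1]}")

# The IR length and DR length should reproduce the planted 199 / 17 exactly;
# coordinates are 1-based inclusive in this printout.
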