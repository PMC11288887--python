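# Synthetic CB-CB distance-bin log-odds profile for loop-helix
# hydrophobic pair scoring.  A constructed surrogate for database-mined
# pair-motif scores: it encodes the canonical contact-distance
# preference of hydrophobic residue pairs (favorable packing around
# 4.5-6.5 A is negative, sub-van-der-Waals approach is penalized,
# scores fade to zero toward the 8 A enumeration cutoff).  The
# selection rule downstream is "total score < 0".
bin_edges: [0.0, 3.5, 4.5, 5.5, 6.5, 7.5, 8.0]
values: [2.0, -0.4, -1.0, -0.8, -0.3, -0.1]
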