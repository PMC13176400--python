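# S1.0 semi-randomized sybody library design (synthetic reconstruction).
#
# This file is a synthetic stand-in for the S1.0 design: the scaffold and the
# per-position amino-acid weights are constructed, not transcribed from the
# published figure, but they reproduce every design-intrinsic count of the
# library: 19 randomized positions; 7 randomized positions in CDR1 + flank
# carrying 32 (position, amino-acid) compositions; 5 in CDR2 (one restricted
# to S/Y/R/E, four fully randomized over the 18-letter alphabet excluding Cys
# and Pro); 7 in CDR3 + flank carrying 97 compositions; isoleucine encoded at
# 20% at display position 29; theoretical diversity 1.13e18.
#
# `allowed` is either a mapping letter -> weight (weights sum to 1) or a plain
# list of letters (equal weights). display_number is the 1-based figure-style
# residue number (position + 1 here).
name: S1.0
scaffold: QVQLVESGGGLVQAGGSLRLSCAASGFTYSYAMGSWYRQAPGKEREWVAGSSTGSDRTNYADSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYCAVGRGYYSGFYEYDYWGQGTQVTVSS
regions:
  - {name: FR1,  start: 0,   end: 25}
  - {name: CDR1, start: 25,  end: 35}
  - {name: FR2,  start: 35,  end: 49}
  - {name: CDR2, start: 49,  end: 58}
  - {name: FR3,  start: 58,  end: 97}
  - {name: CDR3, start: 97,  end: 111}
  - {name: FR4,  start: 111, end: 122}
compositions:
  # CDR1 + flank: 7 positions, 32 compositions
  - position: 26
    display_number: 27
    allowed: {F: 0.40, I: 0.20, V: 0.20, L: 0.20}
  - position: 27
    display_number: 28
    allowed: {T: 0.25, S: 0.25, N: 0.20, D: 0.15, G: 0.15}
  - position: 28
    display_number: 29
    allowed: {Y: 0.30, S: 0.30, I: 0.20, T: 0.20}
  - position: 29
    display_number: 30
    allowed: {S: 0.30, Y: 0.20, R: 0.20, N: 0.15, D: 0.15}
  - position: 30
    display_number: 31
    allowed: {Y: 0.25, W: 0.25, R: 0.20, S: 0.15, G: 0.15}
  - position: 31
    display_number: 32
    allowed: {A: 0.30, M: 0.30, S: 0.20, T: 0.20}
  - position: 33
    display_number: 34
    allowed: {G: 0.25, A: 0.20, S: 0.20, W: 0.20, R: 0.15}
  # CDR2: 5 positions; one surface position restricted to S/Y/R/E, the rest
  # fully randomized over all amino acids except cysteine and proline
  - position: 50
    display_number: 51
    allowed: [A, D, E, F, G, H, I, K, L, M, N, Q, R, S, T, V, W, Y]
  - position: 52
    display_number: 53
    allowed: [A, D, E, F, G, H, I, K, L, M, N, Q, R, S, T, V, W, Y]
  - position: 54
    display_number: 55
    allowed: {S: 0.25, Y: 0.25, R: 0.25, E: 0.25}
  - position: 55
    display_number: 56
    allowed: [A, D, E, F, G, H, I, K, L, M, N, Q, R, S, T, V, W, Y]
  - position: 56
    display_number: 57
    allowed: [A, D, E, F, G, H, I, K, L, M, N, Q, R, S, T, V, W, Y]
  # CDR3 + flank: 7 positions, 97 compositions
  - position: 99
    display_number: 100
    allowed: [A, D, E, F, G, H, I, K, L, M, N, Q, R, S, T, V, W, Y]
  - position: 100
    display_number: 101
    allowed: [A, D, E, F, G, H, I, K, L, M, N, Q, R, S, T, V, W, Y]
  - position: 101
    display_number: 102
    allowed: [A, D, E, F, G, H, I, K, L, M, N, Q, R, S, T, V, W, Y]
  - position: 102
    display_number: 103
    allowed: [A, D, E, F, G, I, K, L, N, Q, R, S, T, V, Y]
  - position: 103
    display_number: 104
    allowed: [A, D, E, F, G, K, N, Q, R, S, T, Y]
  - position: 104
    display_number: 105
    allowed: {G: 0.20, S: 0.15, Y: 0.15, A: 0.10, D: 0.10, N: 0.10, R: 0.10, T: 0.10}
  - position: 106
    display_number: 107
    allowed: {Y: 0.20, W: 0.20, F: 0.15, S: 0.15, D: 0.10, N: 0.10, E: 0.05, H: 0.05}
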