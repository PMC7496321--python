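"""Difficulty annotations for the 56-target cross-docking benchmark set.

Each entry is (complex id, unbound-bound interface C-alpha RMSD in Angstroms,
difficulty class) for the 55 binary complexes of docking benchmark 5 used in
the cross-docking study plus the CAPRI target T131 (6GBG).  The difficulty
class follows the standard thresholds implemented by
:func:`modecross.capri.classify_difficulty`: RB <= 1.35 A, M in (1.35, 2.5],
D > 2.5 A.
"""

from __future__ import annotations

__all__ = ["BENCHMARK_TARGETS"]

BENCHMARK_TARGETS: tuple[tuple[str, float, str], ...] = (
    ("3EOA", 0.39, "RB"), ("3BIW", 0.39, "RB"), ("4M76", 0.43, "RB"),
    ("1JTD", 0.44, "RB"), ("3L5W", 0.48, "RB"), ("3MXW", 0.48, "RB"),
    ("4G6M", 0.49, "RB"), ("3RVW", 0.50, "RB"), ("3PC8", 0.50, "RB"),
    ("3VLB", 0.51, "RB"), ("3P57", 0.53, "RB"), ("2GTP", 0.54, "RB"),
    ("2YVJ", 0.60, "RB"), ("4G6J", 0.61, "RB"), ("1EXB", 0.62, "RB"),
    ("3K75", 0.64, "RB"), ("4H03", 0.68, "RB"), ("2GAF", 0.69, "RB"),
    ("3A4S", 0.72, "RB"), ("3HMX", 0.73, "RB"), ("BP57", 0.74, "RB"),
    ("4GXU", 0.78, "RB"), ("3H2V", 0.80, "RB"), ("4DN4", 0.81, "RB"),
    ("3LVK", 0.81, "RB"), ("4HX3", 0.90, "RB"), ("CP57", 0.91, "RB"),
    ("4FQI", 1.08, "RB"), ("2W9E", 1.13, "RB"), ("1M27", 1.22, "RB"),
    ("2VXT", 1.33, "RB"), ("2X9A", 1.33, "RB"), ("2A1A", 1.35, "RB"),
    ("3EO1", 1.37, "M"), ("3DAW", 1.49, "M"), ("4IZ7", 1.56, "M"),
    ("4LW4", 1.60, "M"), ("4JCV", 1.62, "M"), ("3BX7", 1.63, "M"),
    ("3HI6", 1.65, "M"), ("3S9D", 1.69, "M"), ("3AAA", 1.78, "M"),
    ("3V6Z", 1.83, "M"), ("3G6D", 1.86, "M"), ("3R9A", 1.91, "M"),
    ("BAAD", 2.00, "M"), ("4FZA", 2.04, "M"), ("3SZK", 2.10, "M"),
    ("3L89", 2.51, "D"), ("3F1P", 2.52, "D"), ("3FN1", 3.65, "D"),
    ("3H11", 3.79, "D"), ("1RKE", 4.25, "D"), ("3AAD", 4.37, "D"),
    ("4GAM", 5.79, "D"), ("6GBG", 1.82, "M"),
)
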