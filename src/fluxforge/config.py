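"""Global numeric defaults shared across the package.

All solver-facing code reads these at call time, so a script may adjust them
before running an analysis (e.g. ``fluxforge.config.ZERO_TOL = 1e-8``).
"""

# Flux magnitudes below this are treated as zero (flux units, mmol/gDW/h).
ZERO_TOL: float = 1e-6

# Finite stand-in for an unbounded flux direction.  LP/MILP layers need
# finite big-M values, so infinite bounds are clipped to +/- this at load.
DEFAULT_BOUND: float = 10000.0

# Compartment tokens that mark a species as external (extracellular/boundary).
EXTERNAL_COMPARTMENTS: frozenset = frozenset({"e", "ext", "extracellular", "b"})

# Metabolite-id suffixes that mark a species as external by name.
EXTERNAL_NAME_SUFFIXES: tuple = ("xt", "_ext", "[e]")

# Name fragments used to rank biomass-reaction candidates.
BIOMASS_PATTERNS: tuple = ("biomass", "growth", "vgrowth")

# Fraction of wild-type biomass below which a mutant counts as non-viable.
VIABILITY_THRESHOLD: float = 0.05
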