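"""Physical constants and shared defaults."""

#: Boltzmann constant in kcal/(mol K)
KB = 1.987204259e-3

#: Default simulation temperature (K)
DEFAULT_TEMPERATURE = 298.15

#: kT at the default temperature (kcal/mol), ~0.593
KT_ROOM = KB * DEFAULT_TEMPERATURE

#: Default implicit-constraint steepness mapping theta onto the lambda simplex
DEFAULT_STEEPNESS = 8.0

#: Implicit-constraint activity restraint
#: U_ic = height * sum_i (1 - exp(-lambda_i / alpha)): a saturating count of
#: alchemically active substituents.  It emulates the intrinsic alchemical
#: barriers of partially coupled chemistries: spectator lambdas are pressed
#: to zero (slope height/alpha), mixed intermediates are penalized by one
#: extra 'height' per active substituent, and pure end states differ only
#: by a constant offset.
DEFAULT_IC_HEIGHT = 1.5
DEFAULT_IC_ALPHA = 0.007

#: Default lambda end-state threshold used by counting/estimation
DEFAULT_ENDSTATE_THRESHOLD = 0.99

#: Minimum end-state frames for a substituent to count as sampled
DEFAULT_MIN_COUNT = 10
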