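phase	counter_medium	c	e	s	a	b	v	l	provenance
# TEMPLATE ONLY - the package ships no literature LFER coefficients.
# Populate one row per calibrated system (phase-water or phase-air) from
# the primary literature, delete these comment lines, and cite the source
# in the provenance column. A water-air row (phase=water, counter_medium=air)
# is accepted and normalized to air-water by sign flip at load time.
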