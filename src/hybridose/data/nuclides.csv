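# Physical decay data for therapy nuclides.
# half_life_h: physical half-life in hours.
# mean_beta_keV: mean beta-minus energy emitted per decay (keV).
# extra_electron_keV: conversion + Auger electron energy per decay (keV).
#   Shipped as 0 by default; populate from ICRP-107-style tables if the
#   short-range electron contribution should enter the self-dose.
# photon_lines: semicolon-separated energy_keV:yield pairs (principal gamma lines).
name,half_life_h,mean_beta_keV,extra_electron_keV,photon_lines
Tb161,165.744,154.0,0.0,74.6:0.102;48.9:0.170
Lu177,159.528,133.0,0.0,208.4:0.104;112.9:0.062
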