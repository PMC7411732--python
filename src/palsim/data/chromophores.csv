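# Absorption coefficients of the four tissue chromophores used by the mixture
# model, in mm^-1, on a sparse near-infrared wavelength grid.
# Hemoglobin columns are whole blood at 150 g/L, converted from tabulated molar
# extinction coefficients (compilation by S. Prahl, Oregon Medical Laser Center)
# via mu_a = ln(10) * eps * 150 / 64500 (cm^-1), then /10 to mm^-1.
# Water from the Hale & Querry tabulation; lipid from the soybean-oil
# measurements of van Veen et al. Values rounded; intermediate wavelengths are
# linearly interpolated by the loader.
wavelength_nm,mu_a_HbO2,mu_a_Hb,mu_a_water,mu_a_lipid
700,0.1553,0.9610,0.00060,0.00050
720,0.2121,0.8966,0.00104,0.00060
750,0.2774,0.7525,0.00260,0.00055
760,0.3139,0.8294,0.00280,0.00058
800,0.4371,0.4081,0.00223,0.00090
850,0.5667,0.3703,0.00433,0.00080
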