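# Default optics tables for the RGB modified Beer-Lambert model.
# extinction: molar extinction coefficient [cm^-1 (mol/L)^-1] of each chromophore
#   at a single effective wavelength per camera channel (R 610 nm, G 530 nm,
#   B 470 nm). Values from standard compiled hemoglobin spectra.
# pathlength: SYNTHETIC placeholder mean photon path lengths [cm] per channel and
#   tissue class (order-of-magnitude values; replace with values from a photon
#   transport simulation of the actual imaging geometry for quantitative work).
quantity,channel,key,value
extinction,R,hbo2,1506.0
extinction,G,hbo2,39956.8
extinction,B,hbo2,33209.2
extinction,R,hb,9443.6
extinction,G,hb,39036.4
extinction,B,hb,16156.4
pathlength,R,gray_matter,0.40
pathlength,G,gray_matter,0.15
pathlength,B,gray_matter,0.08
pathlength,R,surface_vessel,0.10
pathlength,G,surface_vessel,0.03
pathlength,B,surface_vessel,0.02
pathlength,R,buried_vessel,0.25
pathlength,G,buried_vessel,0.08
pathlength,B,buried_vessel,0.05
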