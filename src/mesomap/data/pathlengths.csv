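# Differential pathlength factors for dorsal-skull widefield reflectance,
# in cm, per illumination wavelength. Synthetic working values chosen to
# reproduce the qualitative wavelength dependence of photon penetration in
# rodent cortex (longer effective paths at red wavelengths where absorption
# is low); configurable at run time via OpticsModel.
# columns: wavelength_nm, pathlength_cm
wavelength_nm,pathlength_cm
478,0.057
588,0.072
610,0.40
625,0.55
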