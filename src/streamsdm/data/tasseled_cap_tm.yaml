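# Tasseled Cap coefficients for Landsat TM surface/TOA reflectance
# (Crist 1985 reflectance-factor set). Rows map the six optical bands
# (TM 1, 2, 3, 4, 5, 7) to brightness, greenness and wetness.
sensor: landsat_tm_reflectance
bands: [1, 2, 3, 4, 5, 7]
brightness: [0.2043, 0.4158, 0.5524, 0.5741, 0.3124, 0.2303]
greenness: [-0.1603, -0.2819, -0.4934, 0.7940, -0.0002, -0.1446]
wetness: [0.0315, 0.2021, 0.3102, 0.1594, -0.6806, -0.6109]
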