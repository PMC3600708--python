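{
  "name": "msatpipe-11plex",
  "version": "1.0",
  "units": {"sizes": "bp", "primer_conc": "uM"},
  "markers": [
    {"name": "BAT25",   "group": 1, "dye": "FAM", "window_min": 115, "window_max": 145, "repeat_unit": 1, "product_range": [130, 130], "primer_conc": 0.25},
    {"name": "BAT26",   "group": 1, "dye": "HEX", "window_min": 105, "window_max": 135, "repeat_unit": 1, "product_range": [120, 120], "primer_conc": 2.0},
    {"name": "D3S3623", "group": 1, "dye": "FAM", "window_min": 200, "window_max": 230, "repeat_unit": 2, "product_range": [207, 223], "primer_conc": 0.25},
    {"name": "D5S346",  "group": 1, "dye": "NED", "window_min": 70,  "window_max": 115, "repeat_unit": 2, "product_range": null, "primer_conc": null},
    {"name": "D6S262",  "group": 1, "dye": "HEX", "window_min": 160, "window_max": 190, "repeat_unit": 2, "product_range": [167, 183], "primer_conc": 0.5},
    {"name": "D7S481",  "group": 1, "dye": "NED", "window_min": 175, "window_max": 205, "repeat_unit": 2, "product_range": [181, 199], "primer_conc": 0.5},
    {"name": "D2S123",  "group": 2, "dye": "HEX", "window_min": 200, "window_max": 240, "repeat_unit": 2, "product_range": [203, 233], "primer_conc": 1.0},
    {"name": "D3S1262", "group": 2, "dye": "HEX", "window_min": 120, "window_max": 150, "repeat_unit": 2, "product_range": [132, 146], "primer_conc": 2.0},
    {"name": "D9S171",  "group": 2, "dye": "NED", "window_min": 100, "window_max": 130, "repeat_unit": 2, "product_range": [102, 122], "primer_conc": 0.25},
    {"name": "D17S250", "group": 2, "dye": "NED", "window_min": 175, "window_max": 210, "repeat_unit": 2, "product_range": [188, 203], "primer_conc": 0.5},
    {"name": "D18S61",  "group": 2, "dye": "FAM", "window_min": 145, "window_max": 180, "repeat_unit": 2, "product_range": [150, 176], "primer_conc": 0.5}
  ],
  "params": {
    "peak_algorithm": "advanced",
    "sizing_method": "local_southern",
    "min_peak_half_width": {"1": 4, "2": 2},
    "mono_cutoff": 0.95,
    "range_filters": {
      "1": {"FAM": [146, 194], "HEX": [136, 159], "NED": [116, 174]},
      "2": {"FAM": [181, 250], "HEX": [151, 199], "NED": [131, 174]}
    }
  },
  "ladder": {
    "dye": "ROX",
    "sizes": [35, 50, 75, 100, 139, 150, 160, 200, 250, 300, 340, 350, 400, 450, 490, 500]
  }
}
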