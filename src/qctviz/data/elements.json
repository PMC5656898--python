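{
 "version": 1,
 "note": "Element presentation data. color: PyMOL-style element RGB in [0,1] (PyMOL inherits Jmol/CPK colors for elements it does not override). vdw: van der Waals radius in angstrom, Bondi 1964 values; starred elements in Bondi's paper that lack a value use the Mantina 2009 extension. Elements absent here fall back to gray / 2.0 A at the presentation layer.",
 "elements": {
  "H":  {"Z": 1,  "color": [0.9, 0.9, 0.9],    "vdw": 1.20},
  "He": {"Z": 2,  "color": [0.851, 1.0, 1.0],  "vdw": 1.40},
  "Li": {"Z": 3,  "color": [0.8, 0.502, 1.0],  "vdw": 1.82},
  "Be": {"Z": 4,  "color": [0.761, 1.0, 0.0],  "vdw": 1.53},
  "B":  {"Z": 5,  "color": [1.0, 0.710, 0.710],"vdw": 1.92},
  "C":  {"Z": 6,  "color": [0.2, 1.0, 0.2],    "vdw": 1.70},
  "N":  {"Z": 7,  "color": [0.2, 0.2, 1.0],    "vdw": 1.55},
  "O":  {"Z": 8,  "color": [1.0, 0.3, 0.3],    "vdw": 1.52},
  "F":  {"Z": 9,  "color": [0.702, 1.0, 1.0],  "vdw": 1.47},
  "Ne": {"Z": 10, "color": [0.702, 0.890, 0.961], "vdw": 1.54},
  "Na": {"Z": 11, "color": [0.671, 0.361, 0.949], "vdw": 2.27},
  "Mg": {"Z": 12, "color": [0.541, 1.0, 0.0],  "vdw": 1.73},
  "Al": {"Z": 13, "color": [0.749, 0.651, 0.651], "vdw": 1.84},
  "Si": {"Z": 14, "color": [0.941, 0.784, 0.627], "vdw": 2.10},
  "P":  {"Z": 15, "color": [1.0, 0.502, 0.0],  "vdw": 1.80},
  "S":  {"Z": 16, "color": [0.9, 0.775, 0.25], "vdw": 1.80},
  "Cl": {"Z": 17, "color": [0.122, 0.941, 0.122], "vdw": 1.75},
  "Ar": {"Z": 18, "color": [0.502, 0.820, 0.890], "vdw": 1.88},
  "K":  {"Z": 19, "color": [0.561, 0.251, 0.831], "vdw": 2.75},
  "Ca": {"Z": 20, "color": [0.239, 1.0, 0.0],  "vdw": 2.31},
  "Sc": {"Z": 21, "color": [0.902, 0.902, 0.902], "vdw": 2.11},
  "Ti": {"Z": 22, "color": [0.749, 0.761, 0.780], "vdw": 2.00},
  "V":  {"Z": 23, "color": [0.651, 0.651, 0.671], "vdw": 2.00},
  "Cr": {"Z": 24, "color": [0.541, 0.600, 0.780], "vdw": 2.00},
  "Mn": {"Z": 25, "color": [0.612, 0.478, 0.780], "vdw": 2.00},
  "Fe": {"Z": 26, "color": [0.878, 0.400, 0.200], "vdw": 2.00},
  "Co": {"Z": 27, "color": [0.941, 0.565, 0.627], "vdw": 2.00},
  "Ni": {"Z": 28, "color": [0.314, 0.816, 0.314], "vdw": 1.63},
  "Cu": {"Z": 29, "color": [0.784, 0.502, 0.200], "vdw": 1.40},
  "Zn": {"Z": 30, "color": [0.490, 0.502, 0.690], "vdw": 1.39},
  "Ga": {"Z": 31, "color": [0.761, 0.561, 0.561], "vdw": 1.87},
  "Ge": {"Z": 32, "color": [0.400, 0.561, 0.561], "vdw": 2.11},
  "As": {"Z": 33, "color": [0.741, 0.502, 0.890], "vdw": 1.85},
  "Se": {"Z": 34, "color": [1.0, 0.631, 0.0],  "vdw": 1.90},
  "Br": {"Z": 35, "color": [0.651, 0.161, 0.161], "vdw": 1.85},
  "Kr": {"Z": 36, "color": [0.361, 0.722, 0.820], "vdw": 2.02}
 }
}
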