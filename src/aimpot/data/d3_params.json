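{
 "provenance": "SYNTHETIC parameter set. The functional form (coordination-number counting, Gaussian-weighted C6(CN) interpolation, C8 from r4r2 factors, rational Becke-Johnson damping) follows the published 2-body D3(BJ) model; the numeric reference tables here are smooth free-atom-scale stand-ins for the published TDDFT-derived tables, which are not redistributed with this package. Swap this file to use the real tables.",
 "k1": 16.0,
 "k3": 4.0,
 "damping": {
  "b97-3c": {
   "s6": 1.0,
   "s8": 1.5,
   "a1": 0.37,
   "a2": 4.1
  },
  "wb97m": {
   "s6": 1.0,
   "s8": 0.28,
   "a1": 0.57,
   "a2": 3.14
  }
 },
 "elements": {
  "1": {
   "symbol": "H",
   "rcov": 0.32,
   "r4r2": 2.15,
   "c6_refs": [
    [
     0.0,
     7.6
    ],
    [
     1.0,
     6.42322
    ]
   ]
  },
  "5": {
   "symbol": "B",
   "rcov": 0.85,
   "r4r2": 2.582624,
   "c6_refs": [
    [
     0.0,
     99.5
    ],
    [
     1.0,
     84.093475
    ],
    [
     2.0,
     72.09486
    ],
    [
     3.0,
     62.75033
    ]
   ]
  },
  "6": {
   "symbol": "C",
   "rcov": 0.75,
   "r4r2": 2.657321,
   "c6_refs": [
    [
     0.0,
     46.6
    ],
    [
     1.0,
     39.384482
    ],
    [
     2.0,
     33.76503
    ],
    [
     3.0,
     29.388597
    ],
    [
     4.0,
     25.980227
    ]
   ]
  },
  "7": {
   "symbol": "N",
   "rcov": 0.71,
   "r4r2": 2.726013,
   "c6_refs": [
    [
     0.0,
     24.2
    ],
    [
     1.0,
     20.452885
    ],
    [
     2.0,
     17.534629
    ],
    [
     3.0,
     15.261889
    ]
   ]
  },
  "8": {
   "symbol": "O",
   "rcov": 0.63,
   "r4r2": 2.789949,
   "c6_refs": [
    [
     0.0,
     15.6
    ],
    [
     1.0,
     13.184505
    ],
    [
     2.0,
     11.303315
    ]
   ]
  },
  "9": {
   "symbol": "F",
   "rcov": 0.64,
   "r4r2": 2.85,
   "c6_refs": [
    [
     0.0,
     9.5
    ],
    [
     1.0,
     8.029025
    ]
   ]
  },
  "14": {
   "symbol": "Si",
   "rcov": 1.16,
   "r4r2": 3.10958,
   "c6_refs": [
    [
     0.0,
     305.0
    ],
    [
     1.0,
     257.773967
    ],
    [
     2.0,
     220.994296
    ],
    [
     3.0,
     192.350259
    ],
    [
     4.0,
     170.042261
    ]
   ]
  },
  "15": {
   "symbol": "P",
   "rcov": 1.11,
   "r4r2": 3.155544,
   "c6_refs": [
    [
     0.0,
     185.0
    ],
    [
     1.0,
     156.354701
    ],
    [
     2.0,
     134.04572
    ],
    [
     3.0,
     116.671469
    ]
   ]
  },
  "16": {
   "symbol": "S",
   "rcov": 1.03,
   "r4r2": 3.2,
   "c6_refs": [
    [
     0.0,
     134.0
    ],
    [
     1.0,
     113.251513
    ],
    [
     2.0,
     97.092576
    ]
   ]
  },
  "17": {
   "symbol": "Cl",
   "rcov": 0.99,
   "r4r2": 3.243087,
   "c6_refs": [
    [
     0.0,
     94.6
    ],
    [
     1.0,
     79.952188
    ]
   ]
  },
  "33": {
   "symbol": "As",
   "rcov": 1.21,
   "r4r2": 3.810597,
   "c6_refs": [
    [
     0.0,
     246.0
    ],
    [
     1.0,
     207.909495
    ],
    [
     2.0,
     178.24458
    ],
    [
     3.0,
     155.14152
    ]
   ]
  },
  "34": {
   "symbol": "Se",
   "rcov": 1.16,
   "r4r2": 3.840833,
   "c6_refs": [
    [
     0.0,
     210.0
    ],
    [
     1.0,
     177.483715
    ],
    [
     2.0,
     152.160007
    ]
   ]
  },
  "35": {
   "symbol": "Br",
   "rcov": 1.14,
   "r4r2": 3.870628,
   "c6_refs": [
    [
     0.0,
     162.0
    ],
    [
     1.0,
     136.916009
    ]
   ]
  },
  "53": {
   "symbol": "I",
   "rcov": 1.33,
   "r4r2": 4.348038,
   "c6_refs": [
    [
     0.0,
     385.0
    ],
    [
     1.0,
     325.386811
    ]
   ]
  }
 }
}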