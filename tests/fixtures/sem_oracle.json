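{
 "chain": {
  "variables": [
   "X",
   "M",
   "Y"
  ],
  "edges": [
   [
    "X",
    "M"
   ],
   [
    "M",
    "Y"
   ]
  ],
  "n": 150,
  "S": [
   [
    0.9185631125924358,
    0.46957015195640583,
    0.1380908725465842
   ],
   [
    0.46957015195640583,
    0.9391648339699403,
    0.4264829009506382
   ],
   [
    0.1380908725465842,
    0.4264829009506382,
    0.8536889938862517
   ]
  ],
  "oracle": {
   "estimates": {
    "M~X": 0.5112007498658973,
    "M~~M": 0.6991202201751824,
    "Y~M": 0.45410867775771996,
    "Y~~Y": 0.6600194076492808,
    "X~~X": 0.9185631125924358
   },
   "F": 0.012590869694592222,
   "chi2": 1.876039584494241,
   "df": 1,
   "rmsea": 0.07667763884353161,
   "srmr": 0.034643372985660004,
   "cfi": 0.9892104679850697,
   "aic": 1150.6349221094044,
   "bic": 1165.6880985798857,
   "n_free": 5
  }
 },
 "two_route": {
  "variables": [
   "A",
   "T",
   "H",
   "C"
  ],
  "edges": [
   [
    "A",
    "T"
   ],
   [
    "A",
    "H"
   ],
   [
    "T",
    "H"
   ],
   [
    "H",
    "C"
   ],
   [
    "T",
    "C"
   ]
  ],
  "n": 200,
  "S": [
   [
    0.9623844535206258,
    0.6478650098086016,
    -0.647762945803009,
    -0.4521371160880137
   ],
   [
    0.6478650098086016,
    1.0602897281442876,
    -0.7058108089427874,
    -0.626113109384021
   ],
   [
    -0.647762945803009,
    -0.7058108089427874,
    1.0826616493569625,
    0.669840439606843
   ],
   [
    -0.4521371160880137,
    -0.626113109384021,
    0.669840439606843,
    1.0214472626821167
   ]
  ],
  "oracle": {
   "estimates": {
    "T~A": 0.6731873186838804,
    "T~~T": 0.6241552193221291,
    "H~A": -0.38214575250598487,
    "H~T": -0.43217616382003127,
    "H~~H": 0.5300871831959713,
    "C~H": 0.4129294001138545,
    "C~T": -0.3156336108613696,
    "C~~C": 0.5472281102607442,
    "A~~A": 0.9623844535206258
   },
   "F": 0.0014676338509307385,
   "chi2": 0.29205913633521696,
   "df": 1,
   "rmsea": 0.0,
   "srmr": 0.006325096839497574,
   "cfi": 1.0,
   "aic": 1929.2372870111913,
   "bic": 1958.9221433101236,
   "n_free": 9
  }
 },
 "covariate": {
  "variables": [
   "X1",
   "X2",
   "M",
   "Y1",
   "Y2"
  ],
  "edges": [
   [
    "X1",
    "M"
   ],
   [
    "X2",
    "M"
   ],
   [
    "M",
    "Y1"
   ],
   [
    "M",
    "Y2"
   ],
   [
    "X1",
    "Y2"
   ]
  ],
  "n": 120,
  "S": [
   [
    0.8298451729846718,
    0.2890385631365199,
    0.38387914848023924,
    0.330024086927669,
    0.28535142930175894
   ],
   [
    0.2890385631365199,
    0.9949537823639097,
    -0.19835482758158812,
    -0.1299321275554881,
    0.048220834497251744
   ],
   [
    0.38387914848023924,
    -0.19835482758158812,
    0.8342503474930212,
    0.577462872657368,
    0.24761137573374914
   ],
   [
    0.330024086927669,
    -0.1299321275554881,
    0.577462872657368,
    0.8148580284066439,
    0.15382291414321433
   ],
   [
    0.28535142930175894,
    0.048220834497251744,
    0.24761137573374914,
    0.15382291414321433,
    0.9366368208520498
   ]
  ],
  "oracle": {
   "estimates": {
    "M~X1": 0.5919225697892984,
    "M~X2": -0.37131702315237536,
    "M~~M": 0.5333710913305724,
    "Y1~M": 0.6921937454298737,
    "Y1~~Y1": 0.4151418397352462,
    "Y2~M": 0.17605506474795476,
    "Y2~X1": 0.26241950673454495,
    "Y2~~Y2": 0.8181618027415495,
    "X1~~X1": 0.8298451729846718,
    "X1~~X2": 0.2890385631365199,
    "X2~~X2": 0.9949537823639097
   },
   "F": 0.02200919864008455,
   "chi2": 2.6190946381700613,
   "df": 4,
   "rmsea": 0.0,
   "srmr": 0.02104576381077415,
   "cfi": 1.0,
   "aic": 1471.749067328048,
   "bic": 1502.4114764986507,
   "n_free": 11
  }
 }
}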