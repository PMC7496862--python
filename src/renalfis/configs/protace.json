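{
 "name": "ProtACE",
 "resolution": 2001,
 "no_fire_policy": "error",
 "inputs": [
  {
   "name": "glycaemia",
   "units": "mg/dL",
   "universe": [
    40.0,
    300.0
   ],
   "terms": [
    {
     "label": "good",
     "shape": "trapezoidal",
     "points": [
      40.0,
      40.0,
      90.0,
      110.0
     ],
     "left_shoulder": true
    },
    {
     "label": "alarm",
     "shape": "trapezoidal",
     "points": [
      90.0,
      110.0,
      116.0,
      136.0
     ]
    },
    {
     "label": "danger",
     "shape": "trapezoidal",
     "points": [
      116.0,
      136.0,
      300.0,
      300.0
     ],
     "right_shoulder": true
    }
   ]
  },
  {
   "name": "diff_ace",
   "units": "dose steps",
   "universe": [
    0.0,
    4.0
   ],
   "terms": [
    {
     "label": "0",
     "shape": "triangular",
     "points": [
      0.0,
      0.0,
      1.0
     ]
    },
    {
     "label": "1",
     "shape": "triangular",
     "points": [
      0.5,
      1.0,
      2.0
     ]
    },
    {
     "label": "2",
     "shape": "triangular",
     "points": [
      1.5,
      2.0,
      3.0
     ]
    },
    {
     "label": "3",
     "shape": "triangular",
     "points": [
      2.5,
      3.0,
      4.0
     ]
    },
    {
     "label": "4",
     "shape": "triangular",
     "points": [
      3.5,
      4.0,
      4.0
     ]
    }
   ]
  }
 ],
 "output": {
  "name": "proteinuria",
  "units": "mg/24 h",
  "universe": [
   0.0,
   4000.0
  ],
  "terms": [
   {
    "label": "good",
    "shape": "trapezoidal",
    "points": [
     0.0,
     0.0,
     120.0,
     180.0
    ],
    "left_shoulder": true
   },
   {
    "label": "sufficient",
    "shape": "trapezoidal",
    "points": [
     120.0,
     180.0,
     430.0,
     570.0
    ]
   },
   {
    "label": "alterate",
    "shape": "trapezoidal",
    "points": [
     430.0,
     570.0,
     900.0,
     1100.0
    ]
   },
   {
    "label": "alarm",
    "shape": "trapezoidal",
    "points": [
     900.0,
     1100.0,
     2800.0,
     3200.0
    ]
   },
   {
    "label": "danger",
    "shape": "trapezoidal",
    "points": [
     2800.0,
     3200.0,
     4000.0,
     4000.0
    ],
    "right_shoulder": true
   }
  ]
 },
 "rules": [
  {
   "if": [
    [
     "diff_ace",
     "2"
    ]
   ],
   "connective": "AND",
   "then": "sufficient",
   "weight": 1.0
  },
  {
   "if": [
    [
     "glycaemia",
     "good"
    ],
    [
     "diff_ace",
     "1"
    ]
   ],
   "connective": "AND",
   "then": "sufficient",
   "weight": 1.0
  },
  {
   "if": [
    [
     "glycaemia",
     "alarm"
    ],
    [
     "diff_ace",
     "1"
    ]
   ],
   "connective": "AND",
   "then": "alterate",
   "weight": 1.0
  },
  {
   "if": [
    [
     "glycaemia",
     "danger"
    ],
    [
     "diff_ace",
     "1"
    ]
   ],
   "connective": "AND",
   "then": "alarm",
   "weight": 1.0
  },
  {
   "if": [
    [
     "glycaemia",
     "alarm"
    ],
    [
     "diff_ace",
     "3"
    ]
   ],
   "connective": "AND",
   "then": "alarm",
   "weight": 1.0
  },
  {
   "if": [
    [
     "glycaemia",
     "good"
    ],
    [
     "diff_ace",
     "3"
    ]
   ],
   "connective": "AND",
   "then": "alterate",
   "weight": 1.0
  },
  {
   "if": [
    [
     "glycaemia",
     "danger"
    ],
    [
     "diff_ace",
     "4"
    ]
   ],
   "connective": "AND",
   "then": "danger",
   "weight": 1.0
  },
  {
   "if": [
    [
     "glycaemia",
     "good"
    ],
    [
     "diff_ace",
     "0"
    ]
   ],
   "connective": "AND",
   "then": "good",
   "weight": 1.0
  }
 ]
}
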