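{
 "name": "GfrACE",
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
  "name": "gfr",
  "units": "mL/min",
  "universe": [
   0.0,
   130.0
  ],
  "terms": [
   {
    "label": "danger",
    "shape": "trapezoidal",
    "points": [
     0.0,
     0.0,
     12.0,
     18.0
    ],
    "left_shoulder": true
   },
   {
    "label": "alarm4",
    "shape": "triangular",
    "points": [
     12.0,
     18.0,
     42.0
    ]
   },
   {
    "label": "alarm3",
    "shape": "trapezoidal",
    "points": [
     18.0,
     42.0,
     56.0,
     64.0
    ]
   },
   {
    "label": "alarm2",
    "shape": "trapezoidal",
    "points": [
     56.0,
     64.0,
     84.0,
     96.0
    ]
   },
   {
    "label": "good",
    "shape": "trapezoidal",
    "points": [
     84.0,
     96.0,
     130.0,
     130.0
    ],
    "right_shoulder": true
   }
  ]
 },
 "rules": [
  {
   "if": [
    [
     "glycaemia",
     "good"
    ],
    [
     "diff_ace",
     "2"
    ]
   ],
   "connective": "AND",
   "then": "alarm3",
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
     "2"
    ]
   ],
   "connective": "AND",
   "then": "alarm3",
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
   "then": "alarm2",
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
   "then": "alarm2",
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
   "then": "alarm3",
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
     "3"
    ]
   ],
   "connective": "AND",
   "then": "alarm4",
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
     "4"
    ]
   ],
   "connective": "AND",
   "then": "alarm2",
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
  }
 ]
}
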