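{
 "name": "GfrFIS",
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
   "name": "cyclosporine",
   "units": "mg/kg",
   "universe": [
    0.0,
    20.0
   ],
   "terms": [
    {
     "label": "alarm_down",
     "shape": "trapezoidal",
     "points": [
      0.0,
      0.0,
      1.5,
      2.0
     ],
     "left_shoulder": true
    },
    {
     "label": "good",
     "shape": "trapezoidal",
     "points": [
      1.5,
      2.0,
      4.0,
      5.0
     ]
    },
    {
     "label": "sufficient",
     "shape": "trapezoidal",
     "points": [
      4.0,
      5.0,
      8.0,
      11.0
     ]
    },
    {
     "label": "alarm_up",
     "shape": "trapezoidal",
     "points": [
      8.0,
      11.0,
      12.0,
      15.0
     ]
    },
    {
     "label": "danger",
     "shape": "trapezoidal",
     "points": [
      12.0,
      15.0,
      20.0,
      20.0
     ],
     "right_shoulder": true
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
     "danger"
    ],
    [
     "cyclosporine",
     "danger"
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
     "cyclosporine",
     "danger"
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
     "cyclosporine",
     "alarm_up"
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
     "cyclosporine",
     "sufficient"
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
     "cyclosporine",
     "good"
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
     "alarm"
    ],
    [
     "cyclosporine",
     "good"
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
     "danger"
    ],
    [
     "cyclosporine",
     "good"
    ]
   ],
   "connective": "AND",
   "then": "alarm3",
   "weight": 1.0
  }
 ]
}
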