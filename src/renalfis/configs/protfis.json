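{
 "name": "ProtFIS",
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
   "name": "sirolimus",
   "units": "ng/mL",
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
      4.0,
      5.0
     ],
     "left_shoulder": true
    },
    {
     "label": "sufficient",
     "shape": "trapezoidal",
     "points": [
      4.0,
      5.0,
      6.0,
      11.0
     ]
    },
    {
     "label": "good",
     "shape": "triangular",
     "points": [
      6.0,
      11.0,
      12.0
     ]
    },
    {
     "label": "alarm_up",
     "shape": "trapezoidal",
     "points": [
      11.0,
      12.0,
      13.0,
      14.0
     ]
    },
    {
     "label": "danger",
     "shape": "trapezoidal",
     "points": [
      13.0,
      14.0,
      20.0,
      20.0
     ],
     "right_shoulder": true
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
     "glycaemia",
     "good"
    ],
    [
     "sirolimus",
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
     "danger"
    ],
    [
     "sirolimus",
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
     "sirolimus",
     "sufficient"
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
     "sirolimus",
     "alarm_up"
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
     "sirolimus",
     "sufficient"
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
     "good"
    ],
    [
     "sirolimus",
     "alarm_up"
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
     "alarm"
    ],
    [
     "sirolimus",
     "good"
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
     "sirolimus",
     "alarm_down"
    ]
   ],
   "connective": "AND",
   "then": "sufficient",
   "weight": 1.0
  }
 ]
}
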