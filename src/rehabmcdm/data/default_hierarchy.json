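{
  "metadata": {
    "name": "rc_default_hierarchy",
    "version": "1.0",
    "description": "Default criteria system for functional-recovery assessment after rotator cuff repair: three criterion groups, ten criteria c1-c10 with expert percent shares, benefit/cost directions and ordinal point scales."
  },
  "groups": [
    {"id": "gI", "label": "Physical and functional state", "percent": 50},
    {"id": "gII", "label": "Psychoemotional status", "percent": 30},
    {"id": "gIII", "label": "Healthcare organization and routine", "percent": 20}
  ],
  "criteria": [
    {
      "id": "c1", "label": "Pain syndrome", "group": "gI",
      "direct_importance": 0.2, "percent": 40, "direction": "min",
      "sub": [
        {"id": "c1.1", "label": "Intensity of the pain", "percent": 35, "direction": "min",
         "scale": [{"points": 1, "desc": "mild pain"}, {"points": 2, "desc": "moderate pain"},
                   {"points": 3, "desc": "severe"}, {"points": 4, "desc": "most severe pain"}]},
        {"id": "c1.2", "label": "Duration of the pain", "percent": 20, "direction": "min",
         "scale": [{"points": 1, "desc": "<7 days"}, {"points": 2, "desc": "<4 weeks"},
                   {"points": 3, "desc": "<3 month"}, {"points": 4, "desc": "<6 month"},
                   {"points": 5, "desc": ">6 month"}]},
        {"id": "c1.3", "label": "Nature of the pain", "percent": 18, "direction": "max",
         "scale": [{"points": 1, "desc": "intermittent pain"}, {"points": 2, "desc": "dynamic"},
                   {"points": 3, "desc": "sharp"}, {"points": 4, "desc": "intensive"}]},
        {"id": "c1.4", "label": "Dynamic pain", "percent": 12, "direction": "max",
         "scale": [{"points": 1, "desc": "<90 points"}, {"points": 2, "desc": ">90 points"}]},
        {"id": "c1.5", "label": "Pain increasing factors", "percent": 10, "direction": "max",
         "scale": [{"points": 1, "desc": "exercising"}, {"points": 2, "desc": "movements"},
                   {"points": 3, "desc": "position"}, {"points": 4, "desc": "during rest"}]},
        {"id": "c1.6", "label": "Pain decreasing factors", "percent": 5, "direction": "min",
         "scale": [{"points": 1, "desc": "position"}, {"points": 2, "desc": "movements"},
                   {"points": 3, "desc": "during rest"}, {"points": 4, "desc": "exercising"}]}
      ]
    },
    {
      "id": "c2", "label": "Shoulder motor function and disability", "group": "gI",
      "direct_importance": 0.175, "percent": 35, "direction": "max",
      "sub": [
        {"id": "c2.1", "label": "Shoulder ROM", "percent": 40, "direction": "max",
         "scale": [{"points": 1, "desc": "up to (flexion <90, abduction <90)"},
                   {"points": 2, "desc": "over (flexion >95, abduction >95)"}]},
        {"id": "c2.2", "label": "Shoulder muscle strength", "percent": 30, "direction": "max",
         "scale": [{"points": 1, "desc": "0"}, {"points": 2, "desc": "1"},
                   {"points": 3, "desc": "3"}, {"points": 4, "desc": "4 / 5"}]},
        {"id": "c2.3", "label": "Shoulder functioning and disability", "percent": 15, "direction": "min",
         "scale": [{"points": 1, "desc": "0-5"}, {"points": 2, "desc": "6-10"}]},
        {"id": "c2.4", "label": "Shoulder, arm and hand functioning in ADL", "percent": 10, "direction": "min",
         "scale": [{"points": 1, "desc": "<54"}, {"points": 2, "desc": "55-68"},
                   {"points": 3, "desc": "69-85"}, {"points": 4, "desc": "86-100"}]},
        {"id": "c2.5", "label": "Dexterity of movements", "percent": 5, "direction": "max",
         "scale": [{"points": 1, "desc": "<69 blocks"}, {"points": 2, "desc": "70-79 blocks"},
                   {"points": 3, "desc": ">80 blocks"}]}
      ]
    },
    {
      "id": "c3", "label": "Anxiety / Depression", "group": "gII",
      "direct_importance": 0.135, "percent": 35, "direction": "min",
      "scale": [{"points": 1, "desc": "0-7"}, {"points": 2, "desc": "8-10"},
                {"points": 3, "desc": "11-14"}, {"points": 4, "desc": "15-21"}]
    },
    {
      "id": "c4", "label": "Sociodemographic and injury-related characteristics", "group": "gI",
      "direct_importance": 0.125, "percent": 25, "direction": "min",
      "sub": [
        {"id": "c4.1", "label": "Affected muscles", "percent": 40, "direction": "min",
         "scale": [{"points": 1, "desc": "single affected muscle"}, {"points": 2, "desc": "two affected muscles"},
                   {"points": 3, "desc": ">two affected muscles"}]},
        {"id": "c4.2", "label": "Time since surgery", "percent": 30, "direction": "min",
         "scale": [{"points": 1, "desc": "<6 days"}, {"points": 2, "desc": "<2 weeks"},
                   {"points": 3, "desc": "<4 weeks"}, {"points": 4, "desc": ">5 weeks"}]},
        {"id": "c4.3", "label": "Age", "percent": 15, "direction": "min",
         "scale": [{"points": 1, "desc": "55-60"}, {"points": 2, "desc": "61-75"},
                   {"points": 3, "desc": "76-85"}]},
        {"id": "c4.4", "label": "Causes of injury", "percent": 10, "direction": "min",
         "scale": [{"points": 1, "desc": "Trauma"}, {"points": 2, "desc": "Degenerative"}]},
        {"id": "c4.5", "label": "Affected arm", "percent": 5, "direction": "min",
         "scale": [{"points": 1, "desc": "Dominated"}, {"points": 2, "desc": "Not dominated"}]}
      ]
    },
    {
      "id": "c5", "label": "Fear of movements", "group": "gII",
      "direct_importance": 0.105, "percent": 20, "direction": "min",
      "scale": [{"points": 1, "desc": "1-36"}, {"points": 2, "desc": "37-68"}]
    },
    {
      "id": "c6", "label": "Sleep restriction", "group": "gII",
      "direct_importance": 0.06, "percent": 45, "direction": "min",
      "scale": [{"points": 1, "desc": "normal sleep"},
                {"points": 2, "desc": "sleep restriction first week after surgery"},
                {"points": 3, "desc": "sleep restriction during rehabilitation"},
                {"points": 4, "desc": "sleep restriction after activities"}]
    },
    {
      "id": "c7", "label": "Rehabilitation measures (conventional rehabilitation program)", "group": "gIII",
      "direct_importance": 0.08, "percent": 40, "direction": "max",
      "scale": [{"points": 1, "desc": "program not applied / incomplete"},
                {"points": 2, "desc": "conventional complex program applied"}]
    },
    {
      "id": "c8", "label": "Program intensity and duration", "group": "gIII",
      "direct_importance": 0.05, "percent": 20, "direction": "max",
      "scale": [{"points": 1, "desc": "below protocol intensity"},
                {"points": 2, "desc": "full protocol (2-2.5 weeks)"}]
    },
    {
      "id": "c9", "label": "Medicines", "group": "gIII",
      "direct_importance": 0.04, "percent": 25, "direction": "min",
      "scale": [{"points": 1, "desc": "no medication needed"},
                {"points": 2, "desc": "analgesics / anti-inflammatory drugs used"}]
    },
    {
      "id": "c10", "label": "Home activities and exercising intensity", "group": "gIII",
      "direct_importance": 0.03, "percent": 15, "direction": "max",
      "scale": [{"points": 1, "desc": "low home activity"},
                {"points": 2, "desc": "recommended home activity and exercising"}]
    }
  ]
}
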