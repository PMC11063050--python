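{
  "items": {
    "Q1_WR":     {"name": "Word Recall",                    "domain": "memory",       "range": [0, 10]},
    "Q2_COMM":   {"name": "Commands",                       "domain": "language",     "range": [0, 5]},
    "Q3_CP":     {"name": "Constructional Praxis",          "domain": "visuospatial", "range": [0, 5]},
    "Q4_DWR":    {"name": "Delayed Word Recall",            "domain": "memory",       "range": [0, 10]},
    "Q5_NT":     {"name": "Naming Task",                    "domain": "language",     "range": [0, 5]},
    "Q6_IP":     {"name": "Ideational Praxis",              "domain": "visuospatial", "range": [0, 5]},
    "Q7_ORIENT": {"name": "Orientation",                    "domain": "orientation",  "range": [0, 8]},
    "Q8_WRT":    {"name": "Word Recognition Task",          "domain": "memory",       "range": [0, 12]},
    "Q9_RTI":    {"name": "Remembering Test Instructions",  "domain": "memory",       "range": [0, 5]},
    "Q10_SLA":   {"name": "Spoken Language Ability",        "domain": "language",     "range": [0, 5]},
    "Q11_WFD":   {"name": "Word Finding Difficulty",        "domain": "language",     "range": [0, 5]},
    "Q12_COMP":  {"name": "Comprehension",                  "domain": "language",     "range": [0, 5]},
    "Q13_NC":    {"name": "Number Cancellation",            "domain": "attention",    "range": [0, 5]}
  }
}
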