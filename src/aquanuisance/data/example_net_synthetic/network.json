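{
  "nodes": [
    {
      "name": "Activity",
      "states": [
        "swimming",
        "boating",
        "angling",
        "biodiversity",
        "landscape",
        "birdwatching"
      ]
    },
    {
      "name": "Respondent type",
      "states": [
        "resident",
        "visitor"
      ]
    },
    {
      "name": "Macrophyte species",
      "states": [
        "E. nuttallii",
        "J. bulbosus",
        "Ludwigia",
        "P. crassipes",
        "S. sagittifolia"
      ]
    },
    {
      "name": "Macrophyte growth level",
      "states": [
        "very_low",
        "low",
        "medium",
        "high",
        "very_high"
      ]
    },
    {
      "name": "Perception",
      "states": [
        "nuisance",
        "no_nuisance"
      ]
    },
    {
      "name": "Plant management option",
      "states": [
        "no_removal",
        "partial_removal",
        "full_removal"
      ]
    },
    {
      "name": "Ecosystem",
      "states": [
        "lake",
        "river"
      ]
    },
    {
      "name": "Nutrient loading",
      "states": [
        "low",
        "high"
      ]
    },
    {
      "name": "Nutrient availability",
      "states": [
        "low",
        "high"
      ]
    },
    {
      "name": "Light",
      "states": [
        "low",
        "high"
      ]
    },
    {
      "name": "Flow",
      "states": [
        "low",
        "high"
      ]
    },
    {
      "name": "Trophic cascade",
      "states": [
        "weak",
        "strong"
      ]
    },
    {
      "name": "Phytoplankton",
      "states": [
        "low",
        "medium",
        "high"
      ]
    }
  ],
  "edges": [
    [
      "Activity",
      "Perception"
    ],
    [
      "Ecosystem",
      "Flow"
    ],
    [
      "Flow",
      "Phytoplankton"
    ],
    [
      "Light",
      "Phytoplankton"
    ],
    [
      "Macrophyte growth level",
      "Perception"
    ],
    [
      "Macrophyte species",
      "Perception"
    ],
    [
      "Nutrient availability",
      "Phytoplankton"
    ],
    [
      "Nutrient loading",
      "Nutrient availability"
    ],
    [
      "Perception",
      "Plant management option"
    ],
    [
      "Plant management option",
      "Flow"
    ],
    [
      "Plant management option",
      "Light"
    ],
    [
      "Plant management option",
      "Nutrient availability"
    ],
    [
      "Plant management option",
      "Trophic cascade"
    ],
    [
      "Respondent type",
      "Perception"
    ],
    [
      "Trophic cascade",
      "Phytoplankton"
    ]
  ]
}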