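{
  "mi_classes": ["left hand", "right hand", "legs", "tongue"],
  "scenes": ["kitchen", "living room", "bedroom"],
  "tasks": [
    {"scene": "kitchen", "mi": "left hand", "name": "KL-Cooking", "description": "Start kitchen appliances for cooking"},
    {"scene": "kitchen", "mi": "right hand", "name": "KR-Deliver", "description": "Deliver bowls and chopsticks for meal preparation"},
    {"scene": "kitchen", "mi": "legs", "name": "KG-Cleaning", "description": "Assist with cleaning or reaching the sink area"},
    {"scene": "kitchen", "mi": "tongue", "name": "KT-Check", "description": "Check food temperature to ensure it is safe to eat"},
    {"scene": "living room", "mi": "left hand", "name": "LL-Turn on", "description": "Turn on TV or play music for leisure"},
    {"scene": "living room", "mi": "right hand", "name": "LR-Pour", "description": "Pour and serve water or tea to the user"},
    {"scene": "living room", "mi": "legs", "name": "LG-Mobility", "description": "Provide mobility support for standing or walking"},
    {"scene": "living room", "mi": "tongue", "name": "LT-deliver", "description": "Remind or deliver snacks or fruit"},
    {"scene": "bedroom", "mi": "left hand", "name": "BL-Switch", "description": "Turn off lights for sleeping"},
    {"scene": "bedroom", "mi": "right hand", "name": "BR-MedicationAssist", "description": "Deliver medicine and remind for medication schedule"},
    {"scene": "bedroom", "mi": "legs", "name": "BL-WakeSupport", "description": "Assist the user in getting out of bed safely"},
    {"scene": "bedroom", "mi": "tongue", "name": "BT-ServeWater", "description": "Offer water or activate humidifier for hydration"}
  ]
}
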