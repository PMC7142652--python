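{
 "1": {
  "label": "Religious background",
  "states": [
   "Cult terrorism",
   "Islamic terrorism",
   "Christian terrorism",
   "Jewish terrorism",
   "Other"
  ]
 },
 "2": {
  "label": "Region of the perpetrator",
  "states": [
   "Middle East and North Africa",
   "Europe",
   "Americas",
   "South and Southeast Asia",
   "East and Central Asia",
   "Central and North Africa"
  ]
 },
 "3": {
  "label": "Number of members",
  "states": [
   "Less than 50 people",
   "50-500 people",
   "500-5000 people",
   "More than 5000 people"
  ]
 },
 "4": {
  "label": "Average educational level",
  "states": [
   "High",
   "Medium",
   "Low"
  ]
 },
 "5": {
  "label": "Technical background",
  "states": [
   "High level",
   "Middle level",
   "Low level"
  ]
 },
 "6": {
  "label": "Social relations and organisational components",
  "states": [
   "Complex and diverse",
   "Medium",
   "Single"
  ]
 },
 "7": {
  "label": "Whether they have been reported recently",
  "states": [
   "Yes",
   "No",
   "Unknown"
  ]
 },
 "8": {
  "label": "Whether they ever launched chemical attack",
  "states": [
   "Yes",
   "No"
  ]
 },
 "9": {
  "label": "Whether they made a statement or threat",
  "states": [
   "Yes",
   "No"
  ]
 },
 "10": {
  "label": "Source of chemical weapon",
  "states": [
   "Self-made",
   "Occupied inventory or armory",
   "Steal from elsewhere",
   "Black market"
  ]
 },
 "11": {
  "label": "Whether they have technical support",
  "states": [
   "Yes",
   "No"
  ]
 },
 "12": {
  "label": "Whether they have the capabilities of storing and transporting the chemical weapon",
  "states": [
   "Yes",
   "No"
  ]
 },
 "13": {
  "label": "Whether they have the ability to launch the chemical attack",
  "states": [
   "Yes",
   "No"
  ]
 },
 "14": {
  "label": "Weapon types",
  "states": [
   "Irritant agent",
   "Erosive agent",
   "Systemic poison",
   "Neurotoxic agent",
   "Asphyxiating agent",
   "Acid and alkali corrosive weapons",
   "Mixed Poison",
   "Unknown"
  ]
 },
 "15": {
  "label": "Delivery method",
  "states": [
   "Volatile",
   "Water-soluble",
   "Spraying",
   "Explosive dispersion",
   "Send by post",
   "Unknown"
  ]
 },
 "16": {
  "label": "Chemical dose",
  "states": [
   "Large",
   "Medium",
   "Little",
   "Unknown"
  ]
 },
 "17": {
  "label": "Population density",
  "states": [
   ">1000/km^2",
   "500-1000/km^2",
   "<500/km^2"
  ]
 },
 "18": {
  "label": "Population movement",
  "states": [
   "High",
   "Medium",
   "Low"
  ]
 },
 "19": {
  "label": "Traffic condition",
  "states": [
   "Good",
   "Bad"
  ]
 },
 "20": {
  "label": "Location",
  "states": [
   "Residential area",
   "Commercial area",
   "Open space"
  ]
 },
 "21": {
  "label": "Whether it is a high-value target",
  "states": [
   "Yes",
   "No"
  ]
 },
 "22": {
  "label": "Wind speed",
  "states": [
   "<=2 m/s",
   "2 m/s ~ 4 m/s",
   ">4 m/s"
  ]
 },
 "23": {
  "label": "Wind direction",
  "states": [
   "Upwind",
   "Downwind"
  ]
 },
 "24": {
  "label": "Precipitation",
  "states": [
   "Heavy",
   "Medium",
   "Less",
   "Minimal or dry"
  ]
 },
 "25": {
  "label": "Patrol",
  "states": [
   "More than 2 times",
   "Less than 2 times"
  ]
 },
 "26": {
  "label": "Security check",
  "states": [
   "Yes",
   "No"
  ]
 },
 "27": {
  "label": "Surveillance",
  "states": [
   "24 h",
   "Non-24 h"
  ]
 },
 "28": {
  "label": "Police investigation",
  "states": [
   "Yes",
   "No"
  ]
 },
 "29": {
  "label": "Hospital emergency response",
  "states": [
   "On time",
   "Delay"
  ]
 },
 "30": {
  "label": "Fire emergency response",
  "states": [
   "On time",
   "Delay"
  ]
 },
 "31": {
  "label": "Police emergency response",
  "states": [
   "On time",
   "Delay"
  ]
 },
 "A": {
  "label": "Influence of the terrorist organisation",
  "states": [
   "Large",
   "Medium",
   "Small"
  ]
 },
 "B": {
  "label": "Activity level of the terrorist organisation",
  "states": [
   "Inactive",
   "Active",
   "Very active"
  ]
 },
 "C": {
  "label": "Difficulty in obtaining and using the chemical weapon",
  "states": [
   "Low",
   "Medium",
   "High"
  ]
 },
 "D": {
  "label": "Danger level of the chemical weapon",
  "states": [
   "High",
   "Medium",
   "Low"
  ]
 },
 "E": {
  "label": "Target attraction",
  "states": [
   "High",
   "Medium",
   "Low"
  ]
 },
 "F": {
  "label": "Weather condition",
  "states": [
   "Favorable",
   "Unfavorable"
  ]
 },
 "G": {
  "label": "Prevention ability of the police",
  "states": [
   "High",
   "Medium",
   "Low"
  ]
 },
 "H": {
  "label": "Ability of the emergency response",
  "states": [
   "High",
   "Medium",
   "Low"
  ]
 },
 "I": {
  "label": "Threat of the terrorist organisation",
  "states": [
   "Large",
   "Medium",
   "Small"
  ]
 },
 "J": {
  "label": "Whether the attack is successful",
  "states": [
   "Yes",
   "No"
  ]
 },
 "K": {
  "label": "Casualties",
  "states": [
   "Minor",
   "Medium",
   "Major"
  ]
 }
}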