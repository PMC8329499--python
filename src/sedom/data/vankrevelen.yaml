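# Default van Krevelen compound-class windows (evaluation order = priority).
# Interval strings use standard open/closed notation on O/C and H/C ratios.
- {name: lipids, oc: "(0,0.3]", hc: "[1.5,2]", priority: 1}
- {name: aliphatic/proteins, oc: "[0.3,0.67)", hc: "[1.5,2.2]", priority: 2}
- {name: lignins/CRAM-like, oc: "[0.1,0.67]", hc: "[0.7,1.5]", priority: 3}
- {name: carbohydrates, oc: "(0.67,1.2]", hc: "[1.5,2.4]", priority: 4}
- {name: unsaturated hydrocarbons, oc: "[0.7,1.5]", hc: "(0,0.1]", priority: 5}
- {name: aromatic, oc: "(0,0.67]", hc: "[0.2,0.7)", priority: 6}
- {name: tannins, oc: "(0.67,1]", hc: "[0.6,1.5]", priority: 7}
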