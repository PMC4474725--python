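subject,BST,LR,RF,SVM,LDA,QDA,MLP
S01,80.5,82.39,79.25,77.36,74.21,60.38,83.65
S02,77.96,83.89,79.26,83.52,81.11,72.41,82.22
S03,78.15,78.15,77.78,77.78,76.48,72.22,76.67
S04,61.84,68.86,65.35,64.91,75.88,58.77,69.3
S05,51.84,58.37,54.29,59.18,55.92,55.51,58.37
S06,54.35,53.48,51.74,45.22,49.13,46.52,51.74
S07,90.88,94.79,92.83,94.14,94.46,83.39,94.46
S08,86.45,91.58,85.71,85.71,87.18,76.56,85.71
S09,79.68,82.87,80.48,80.88,82.07,60.96,83.27
S10,70.69,72.84,76.29,70.69,71.55,64.66,71.12
S11,83.91,83.48,86.52,80.87,80.87,67.83,80.0
S12,82.45,86.12,82.86,86.12,76.33,68.57,83.67
S13,71.53,60.85,73.31,61.57,50.89,26.33,58.01
S14,53.36,54.42,51.24,57.6,32.86,25.8,54.77
S15,83.15,86.81,82.78,78.02,50.55,27.47,83.15
S16,32.02,41.23,45.18,36.84,35.53,30.26,34.65
S17,33.33,40.58,35.14,41.67,28.26,28.26,38.77
S18,24.65,26.98,26.05,25.58,27.91,26.98,26.05
S19,64.98,56.32,71.48,64.26,32.49,31.41,60.29
S20,54.98,61.62,63.47,62.36,37.27,31.0,61.62
S21,46.97,39.39,56.44,45.08,41.29,25.0,44.32
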