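electrode,scalp_mean_x,scalp_sd_x,scalp_mean_y,scalp_sd_y,scalp_mean_z,scalp_sd_z,cortex_mean_x,cortex_sd_x,cortex_mean_y,cortex_sd_y,cortex_mean_z,cortex_sd_z
AF3,-31.55,4.56,65.1,4.78,44.6,5.99,-25.41,3.99,54.96,4.57,36.6,5.37
AF4,34.61,4.76,65.6,4.94,42.92,7.92,28.06,4.42,55.43,4.28,35.32,6.42
AF7,-53.89,3.69,59.55,4.31,8.52,6.68,-45.43,4.04,52.57,3.71,7.20,6.01
AF8,55.41,4.14,59.76,4.68,10.20,8.88,46.40,3.81,52.38,4.23,8.78,8.23
AFZ,0.50,4.55,70.36,4.65,50.59,7.57,0.63,3.84,57.98,4.52,41.08,6.31
C1,-31.55,4.94,-21.59,7.43,92.04,3.41,-25.56,4.77,-23.82,6.77,75.26,2.61
C2,28.95,5.68,-21.98,7.47,94.55,3.36,23.84,4.52,-24.31,6.80,78.00,3.21
C3,-59.99,4.12,-19.25,7.40,70.68,4.65,-50.88,4.53,-21.18,6.81,59.95,3.47
C4,58.97,4.73,-21.28,6.98,73.84,5.65,50.78,4.61,-23.18,6.17,63.58,4.78
C5,-76.99,2.19,-19.50,6.26,37.19,5.91,-66.15,3.20,-20.58,5.71,33.83,5.35
C6,77.83,2.15,-21.23,5.94,39.99,8.02,66.48,3.11,-21.77,5.42,36.16,6.97
CP1,-32.35,5.32,-51.50,7.52,89.76,3.69,-25.64,4.41,-48.14,5.73,71.46,3.43
CP2,29.61,4.72,-52.43,7.98,92.91,3.01,24.46,3.97,-49.71,6.28,75.38,3.28
CP3,-59.90,4.74,-49.84,7.27,69.31,5.29,-49.15,4.81,-47.78,5.87,58.42,3.80
CP4,56.54,4.27,-51.89,7.07,73.89,5.87,46.66,4.34,-48.71,5.69,62.98,4.35
CP5,-74.32,2.58,-49.33,6.09,37.02,8.16,-63.88,3.49,-47.19,5.69,33.95,7.01
CP6,73.44,2.21,-52.25,5.56,41.24,7.95,62.43,3.13,-49.07,4.98,37.65,6.65
CPZ,-1.60,4.97,-53.38,7.80,96.60,2.90,-0.73,4.32,-50.47,6.59,75.85,3.31
CZ,-1.09,4.43,-22.15,7.70,99.93,2.66,-0.47,3.61,-24.64,6.88,80.16,3.89
F1,-25.78,4.61,39.37,6.27,72.50,4.61,-20.48,4.35,32.36,5.57,59.68,5.07
F2,26.17,4.41,39.90,6.01,73.75,5.62,20.96,3.78,32.86,5.37,59.93,5.04
F3,-46.04,3.84,40.62,6.37,55.73,5.58,-38.23,3.74,34.47,5.99,46.92,5.14
F4,46.51,4.77,41.51,5.70,57.56,7.15,38.59,4.31,34.99,5.03,48.23,5.93
F5,-59.99,2.80,40.30,4.91,33.12,6.10,-50.82,3.08,35.00,4.51,28.66,5.50
F6,62.13,3.71,39.34,5.05,34.98,7.61,52.34,3.67,33.9,4.35,30.57,6.51
F7,-68.45,2.60,35.32,4.52,4.68,5.56,-56.68,2.82,30.5,4.28,4.33,5.10
F8,71.6,3.03,32.35,5.26,6.88,8.00,59.39,3.04,27.37,4.67,6.97,6.98
FC1,-29.94,4.43,10.07,7.18,84.65,4.01,-24.69,4.32,5.73,6.43,71.11,3.45
FC2,28.88,4.51,9.22,6.47,86.09,4.06,24.09,4.01,5.40,6.14,72.18,3.55
FC3,-53.84,3.95,10.76,6.85,65.67,5.19,-46.09,4.07,7.35,6.76,56.46,4.20
FC4,54.9,4.41,10.08,5.90,67.56,5.81,47.52,4.25,6.49,5.70,58.34,5.18
FC5,-71.6,2.29,11.83,5.91,34.94,5.11,-61.1,2.74,8.02,5.28,30.64,5.07
FC6,73.25,3.46,9.72,4.52,38.28,8.03,62.59,3.44,6.62,4.52,33.69,7.09
FCZ,0.02,3.73,11.38,6.8,91.62,3.31,0.41,3.01,6.77,6.27,75.19,4.06
FP1,-29.72,5.00,77.81,2.42,13.85,7.37,-24.54,4.48,66.41,2.57,11.97,6.81
FP2,29.87,5.19,78.59,3.18,14.59,9.50,25.25,4.43,66.62,2.86,12.19,7.77
FPZ,-0.36,5.19,83.18,2.18,16.67,8.54,-0.29,4.56,69.71,2.39,13.71,7.35
FT10,78.78,1.80,0.51,5.48,-32.1,8.41,60.47,5.25,-1.67,5.63,-31.19,8.88
FT7,-77.03,2.10,8.63,5.19,2.98,6.14,-63.49,3.62,5.75,4.43,3.02,5.36
FT8,79.96,1.76,5.11,4.37,5.06,8.60,66.54,2.85,2.58,3.83,4.93,8.12
FT9,-77.33,2.65,1.91,5.8,-31.28,6.38,-59.09,6.18,0.07,5.75,-30.94,5.82
FZ,0.52,4.56,43.05,6.34,77.99,5.14,0.88,3.46,34.43,5.64,62.21,4.84
O1,-31.42,5.64,-109.90,3.25,8.94,11.50,-27.11,4.68,-99.78,3.60,6.68,10.44
O2,26.35,4.88,-110.54,2.94,11.57,11.31,22.51,4.30,-100.07,2.74,8.94,10.18
OZ,-2.53,5.50,-114.61,2.37,11.90,11.48,-2.49,4.97,-102.67,3.09,9.10,10.31
P1,-31.55,5.73,-77.61,6.82,75.8,6.59,-25.9,4.45,-68.45,5.63,61.21,4.51
P2,24.99,5.99,-78.59,6.65,77.65,6.53,20.8,5.18,-69.28,6.73,64.82,4.87
P3,-52.00,5.32,-77.05,6.86,58.59,8.51,-42.75,4.45,-69.51,6.00,49.82,5.89
P4,47.39,4.70,-78.76,6.04,61.12,7.89,39.28,4.64,-70.63,5.65,52.38,6.17
P5,-63.26,3.79,-77.35,5.62,30.97,9.72,-53.84,3.61,-71.50,5.22,28.15,8.21
P6,60.40,3.56,-78.77,5.00,36.36,9.56,51.14,3.76,-71.81,4.69,32.06,8.35
P7,-69.63,3.32,-73.74,4.90,0.78,10.60,-59.17,2.82,-69.14,4.46,0.70,10.07
P8,67.72,2.35,-75.60,4.69,5.83,9.92,57.52,2.74,-70.05,4.18,4.98,9.43
PO3,-34.84,5.56,-98.67,5.19,41.77,9.39,-29.71,4.39,-88.53,5.70,35.13,8.07
PO4,29.24,5.60,-98.85,4.95,45.00,9.87,25.37,4.62,-88.73,5.24,38.16,8.93
PO7,-54.12,4.43,-93.91,3.75,4.79,10.26,-46.45,3.26,-86.74,3.80,3.87,9.43
PO8,50.17,3.84,-95.92,4.15,8.99,10.35,42.78,4.03,-88.05,3.60,7.87,9.83
POZ,-3.28,5.69,-101.06,5.15,50.6,9.14,-2.76,4.79,-90.20,5.71,42.12,7.54
PZ,-2.25,6.16,-80.03,7.27,79.64,6.14,-1.94,5.31,-69.12,7.17,66.04,4.54
T7,-81.12,1.60,-20.17,5.89,0.58,7.98,-69.72,2.66,-20.31,5.20,0.55,7.35
T8,83.15,1.08,-23.69,6.09,4.20,9.23,71.04,2.95,-23.53,5.69,3.60,8.61
TP7,-78.17,1.68,-49.26,4.7,0.60,9.15,-68.19,2.19,-47.06,4.03,0.35,8.25
TP8,78.51,1.70,-52.05,5.25,3.53,8.75,67.73,2.45,-48.93,5.09,2.77,7.97
TP9,-73.37,2.16,-54.91,4.44,-35.64,8.25,-57.93,4.26,-52.6,3.11,-33.16,7.65
TP10,73.87,2.55,-57.04,4.38,-33.84,10.41,58.93,3.95,-53.09,3.59,-31.33,9.05
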