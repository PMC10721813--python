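model,series,rmse,mape
ARIMA,wheat,241.79,5.33
ARIMA,sugarcane,4542.02,4.74
ARIMA,groundnut,529.45,27.34
ARIMAX,wheat,203.23,4.82
ARIMAX,sugarcane,4444.58,4.37
ARIMAX,groundnut,460.83,22.47
TDNN,wheat,224.71,5.65
TDNN,sugarcane,4952.37,4.44
TDNN,groundnut,510.83,26.06
NLSVR,wheat,315.85,8.16
NLSVR,sugarcane,7224.47,6.85
NLSVR,groundnut,526.28,25.94
WNN,wheat,210.24,5.66
WNN,sugarcane,4922.32,4.49
WNN,groundnut,490.05,23.03
CNN,wheat,227.87,5.82
CNN,sugarcane,6201.06,6.19
CNN,groundnut,470.88,23.06
RNN,wheat,209.64,5.57
RNN,sugarcane,4808.26,4.32
RNN,groundnut,447.08,23.39
LSTM,wheat,215.31,5.36
LSTM,sugarcane,4710.83,4.20
LSTM,groundnut,444.03,22.19
ARIMAX-TDNN,wheat,197.98,4.64
ARIMAX-TDNN,sugarcane,4433.56,4.38
ARIMAX-TDNN,groundnut,459.13,22.35
ARIMAX-NLSVR,wheat,203.36,4.77
ARIMAX-NLSVR,sugarcane,4347.60,4.32
ARIMAX-NLSVR,groundnut,459.14,22.36
ARIMAX-WNN,wheat,195.39,4.47
ARIMAX-WNN,sugarcane,4196.79,4.35
ARIMAX-WNN,groundnut,441.56,21.55
ARIMAX-CNN,wheat,196.37,4.46
ARIMAX-CNN,sugarcane,4239.21,4.23
ARIMAX-CNN,groundnut,453.33,21.76
ARIMAX-RNN,wheat,195.04,4.56
ARIMAX-RNN,sugarcane,4197.64,4.28
ARIMAX-RNN,groundnut,454.92,21.87
ARIMAX-LSTM,wheat,190.68,4.25
ARIMAX-LSTM,sugarcane,4125.26,4.16
ARIMAX-LSTM,groundnut,438.58,21.12
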