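endpoint,dose_mg_L,n,mean_pct,sd_pct
cm_1dpf,0.0,6,6.11,2.36
cm_1dpf,0.5,6,8.56,4.45
cm_1dpf,1.0,6,8.00,4.56
cm_1dpf,4.0,6,10.00,9.78
cm_1dpf,10.0,6,13.00,8.99
cm_1dpf,20.0,6,23.93,6.27
cm_1dpf,50.0,6,24.44,7.79
cm_1dpf,80.0,6,35.00,10.90
cm_1dpf,100.0,6,33.89,7.13
cm_1dpf,120.0,6,46.11,2.51
cm_1dpf,150.0,6,42.78,9.29
cm_1dpf,200.0,6,54.45,16.82
cm_1dpf,250.0,6,66.67,5.27
cm_1dpf,300.0,6,100.00,0
cm_2dpf,0.0,6,10.67,3.82
cm_2dpf,0.5,6,10.89,3.54
cm_2dpf,1.0,6,9.33,3.50
cm_2dpf,4.0,6,10.56,9.78
cm_2dpf,10.0,6,13.17,8.73
cm_2dpf,20.0,6,24.93,7.74
cm_2dpf,50.0,6,51.11,24.10
cm_2dpf,80.0,6,51.11,16.29
cm_2dpf,100.0,6,61.11,29.34
cm_2dpf,120.0,6,76.11,15.41
cm_2dpf,150.0,6,76.67,22.11
cm_2dpf,200.0,6,98.33,2.79
cm_2dpf,250.0,6,100.00,0
cm_2dpf,300.0,6,100.00,0
cm_3dpf,0.0,6,10.67,3.82
cm_3dpf,0.5,6,10.89,3.54
cm_3dpf,1.0,6,9.33,3.50
cm_3dpf,4.0,6,10.56,9.78
cm_3dpf,10.0,6,13.17,8.73
cm_3dpf,20.0,6,25.43,8.21
cm_3dpf,50.0,6,51.11,24.10
cm_3dpf,80.0,6,57.78,22.77
cm_3dpf,100.0,6,85.00,17.98
cm_3dpf,120.0,6,83.89,14.21
cm_3dpf,150.0,6,98.33,4.08
cm_3dpf,200.0,6,99.45,1.36
cm_3dpf,250.0,6,100.00,0
cm_3dpf,300.0,6,100.00,0
cm_4dpf,0.0,6,10.67,3.82
cm_4dpf,0.5,6,10.89,3.54
cm_4dpf,1.0,6,9.33,3.50
cm_4dpf,4.0,6,10.56,9.78
cm_4dpf,10.0,6,14.17,8.33
cm_4dpf,20.0,6,26.26,7.72
cm_4dpf,50.0,6,60.56,22.75
cm_4dpf,80.0,6,78.33,19.41
cm_4dpf,100.0,6,97.22,3.90
cm_4dpf,120.0,6,90.00,10.75
cm_4dpf,150.0,6,100.00,0
cm_4dpf,200.0,6,100.00,0
cm_4dpf,250.0,6,100.00,0
cm_4dpf,300.0,6,100.00,0
cm_5dpf,0.0,6,13.89,3.28
cm_5dpf,0.5,6,14.78,3.99
cm_5dpf,1.0,6,14.56,4.39
cm_5dpf,4.0,6,12.22,10.30
cm_5dpf,10.0,6,16.83,8.52
cm_5dpf,20.0,6,27.93,11.10
cm_5dpf,50.0,6,66.67,16.73
cm_5dpf,80.0,6,85.56,7.50
cm_5dpf,100.0,6,100.00,0
cm_5dpf,120.0,6,100.00,0
cm_5dpf,150.0,6,100.00,0
cm_5dpf,200.0,6,100.00,0
cm_5dpf,250.0,6,100.00,0
cm_5dpf,300.0,6,100.00,0
cma_5dpf,0.0,6,9.45,3.10
cma_5dpf,0.5,6,10.66,5.38
cma_5dpf,1.0,6,10.56,8.43
cma_5dpf,4.0,6,8.55,8.49
cma_5dpf,10.0,6,16.98,4.34
cma_5dpf,20.0,6,24.86,9.23
cma_5dpf,50.0,6,27.46,10.06
cma_5dpf,80.0,6,87.24,12.26
cma_5dpf,100.0,6,100.00,0
cma_5dpf,120.0,6,90.00,10.75
cma_5dpf,150.0,6,100.00,0
cma_5dpf,200.0,6,100.00,0
cma_5dpf,250.0,6,100.00,0
cma_5dpf,300.0,6,100.00,0
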