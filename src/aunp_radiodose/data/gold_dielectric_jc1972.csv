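wavelength_nm,eps_real,eps_imag
187.855,-0.091221,2.734700
191.629,-0.054809,2.839080
195.251,-0.086976,2.917880
199.332,-0.100901,3.027420
203.253,-0.093129,3.166960
207.331,-0.087516,3.312160
211.939,-0.132500,3.510000
216.377,-0.233769,3.606200
221.400,-0.346329,3.710200
226.249,-0.415500,3.825200
231.314,-0.551009,3.892200
237.063,-0.616896,4.055040
242.631,-0.744529,4.163280
248.964,-0.891261,4.338460
255.112,-1.080444,4.490080
261.570,-1.236501,4.722300
268.946,-1.346409,4.976280
276.134,-1.366509,5.282420
284.367,-1.332261,5.494860
292.416,-1.306784,5.596440
300.933,-1.227421,5.780340
310.737,-1.242549,5.792580
320.373,-1.230804,5.845840
331.509,-1.355289,5.573680
342.498,-1.310241,5.538160
354.241,-1.231956,5.598000
367.906,-1.400625,5.609200
381.490,-1.604889,5.644360
397.385,-1.649404,5.738880
413.281,-1.702164,5.717360
430.501,-1.692204,5.649200
450.852,-1.758996,5.282640
471.423,-1.702701,4.844380
495.937,-2.278289,3.812640
520.942,-3.946161,2.580440
548.603,-5.842125,2.111300
582.085,-8.112669,1.660540
616.837,-10.661884,1.374240
659.490,-13.648209,1.035160
704.456,-16.817709,1.066780
756.001,-20.610164,1.271760
821.087,-25.811289,1.626560
891.973,-32.040669,1.925420
984.002,-40.274100,2.794000
1087.581,-51.049600,3.861000
1215.531,-66.218525,5.701500
1393.081,-90.426461,8.186340
1610.184,-125.350500,12.555200
1937.253,-189.042000,25.355200
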