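el comité acordó que el nuevo edificio de la biblioteca abriría al público a principios de la primavera del próximo año
muchos de los estudiantes descubrieron que la práctica y la paciencia eran más importantes que el talento natural para aprender a tocar el piano
después de la larga sequía los agricultores del valle se alegraron de ver caer la lluvia durante toda la noche
ella explicó que los resultados del experimento no eran fiables hasta que las mediciones se repitieran varias veces
el viejo puente sobre el río estaba cerrado por obras y el tráfico de la mañana avanzaba despacio por las calles estrechas
según el informe el número de personas que van al trabajo en bicicleta casi se ha duplicado en los últimos diez años
él pensaba que la reunión terminaría antes de comer pero la discusión continuó hasta bien entrada la tarde
el pequeño museo junto al puerto guarda una colección notable de fotografías de los primeros años de la industria pesquera
cuando se fue la luz durante la tormenta la familia encendió velas y contó historias en la cocina hasta medianoche
el médico le aconsejó hacer ejercicio suave cada día y evitar pasar horas sentado en el escritorio sin descanso
una fina capa de nieve cubría el jardín y los niños salieron antes del desayuno a hacer un muñeco
la periodista pasó tres meses viajando por la región recogiendo entrevistas para su libro sobre la vida del pueblo
desde el primer ensayo quedó claro que la orquesta necesitaba más tiempo para preparar el difícil segundo movimiento
el ayuntamiento prometió que los columpios dañados del parque serían sustituidos antes del comienzo de las vacaciones de verano
casi todos los visitantes suben a la torre por las vistas pero pocos observan las figuras de piedra sobre la puerta occidental
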